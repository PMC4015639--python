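# Synthetic illustrative fee schedule — NOT any country's reimbursement data.
# Fees are round numbers chosen so every model behaviour (crossing in (0,1),
# cost crossing, sensitivity shifts) is exercised; replace the costs section
# with transcribed payer fees to analyse a real health-care system.
country_label: Synthetic example
provenance_note: synthetic illustrative fees, not transcribed from any source
costs:
  f_cmr: 1000
  f_cxa_outpatient: 2000
  f_cxa_inpatient: 3500
  f_ffr: 600
  c_complication: 10000
  discount_rate: 0.03
  horizon_years: 10
  currency: XXX
  cxa_setting: outpatient
performance: {}   # literature defaults: sn_cmr 0.88, sp_cmr 0.90, ndx 0.05, ...
link:
  form: identity
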