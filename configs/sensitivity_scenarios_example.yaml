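# One-way sensitivity scenarios mirroring the standard perturbation classes:
# test/complication fees +-10%, CXA complication rate doubled, CMR accuracy
# changed, false-negative complication rate doubled, CXA setting swapped.
- label: CMR fee +10%
  parameter_path: costs.f_cmr
  perturbation: relative_scale
  magnitude: 1.10
- label: CMR fee -10%
  parameter_path: costs.f_cmr
  perturbation: relative_scale
  magnitude: 0.90
- label: CXA fee +10%
  parameter_path: costs.f_cxa_outpatient
  perturbation: relative_scale
  magnitude: 1.10
- label: FFR fee +10%
  parameter_path: costs.f_ffr
  perturbation: relative_scale
  magnitude: 1.10
- label: complication cost +10%
  parameter_path: costs.c_complication
  perturbation: relative_scale
  magnitude: 1.10
- label: CXA complication rate doubled
  parameter_path: perf.r_cxa
  perturbation: relative_scale
  magnitude: 2.0
- label: CMR sensitivity set to 0.80
  parameter_path: perf.sn_cmr
  perturbation: absolute_set
  magnitude: 0.80
- label: CMR specificity -10%
  parameter_path: perf.sp_cmr
  perturbation: relative_scale
  magnitude: 0.90
- label: FN complication rate doubled
  parameter_path: perf.r_f
  perturbation: relative_scale
  magnitude: 2.0
- label: CXA as inpatient
  perturbation: swap_setting
  setting: inpatient
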