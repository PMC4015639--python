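# cadcea

Decision-analytic cost-effectiveness comparison of two work-ups for suspected
significant coronary artery disease (CAD), from the third-party-payer
perspective:

* **Strategy 1 (CMR + CXA)** — perfusion cardiovascular magnetic resonance
  (CMR) in every patient, followed by invasive coronary angiography (CXA)
  only in ischemia-positive patients;
* **Strategy 2 (CXA + FFR)** — CXA in every patient, followed by a fractional
  flow reserve (FFR) measurement in patients with a ≥50% diameter stenosis.

The package is for health-economics analysts and imaging researchers who want
to know *at which pre-test likelihood of disease an invasive-first work-up
becomes the cheaper way to buy a correct diagnosis*, and how that threshold
moves when fees, complication rates or test accuracy change.

## The model

For a cohort with pre-test likelihood `P_isch` of hemodynamically significant
CAD (the FFR ≤ 0.75 reference standard), effectiveness is the expected
fraction of patients correctly identified as diseased with full coronary
anatomy. With CMR sensitivity `Sn_CMR`, specificity `Sp_CMR` and
non-diagnostic rate `NDx` (non-diagnostic patients cross over to the
invasive reference pathway and are diagnosed with accuracy 1):

```
E1(P_isch) = P_isch · (Sn_CMR·(1 − NDx) + NDx)
E2(P_isch) = P_isch                               (CXA and FFR are the reference)
```

Expected cost per patient tested sums the first-line fee and the subsequent
costs: CXA (fee `F_CXA`, major-complication risk `R_CXA` costed at `C`) for
every CMR-positive patient (true and false positives alike), the full
invasive work-up for the non-diagnostic fraction, and for false negatives the
present value of a complication occurring with probability `R_F` over a
10-year horizon, discounted annually at 3% assuming a uniform event year:

```
C1(P) = F_CMR
      + (1−NDx)·[Sn_CMR·P + (1−Sp_CMR)·(1−P)]·(F_CXA + R_CXA·C)
      + (1−NDx)·(1−Sn_CMR)·P·C·R_F·(1/H)·Σ_{t=1..H}(1+d)^−t
      + NDx·C2(P)
C2(P) = F_CXA + P_sten(P)·F_FFR + R_CXA·C
```

where `P_sten(P)` is a calibrated monotone link from ischemia prevalence to
≥50%-stenosis prevalence (the FFR referral fraction; identity by default).
The cost-effectiveness ratio of a strategy is `CER = C / E`, cost per patient
correctly diagnosed; the **crossing point** is the prevalence where
`CER1 = CER2`, located by a fine grid scan plus Brent root refinement. A
patient-level microsimulation samples individual patients with exactly these
probabilities and serves as an independent oracle for the closed forms.

## Worked example

The repository ships a clearly-labelled **synthetic** fee schedule
(`configs/synthetic_example.yaml`: CMR 1000, outpatient CXA 2000, incremental
FFR 600, complication 10000, identity link); it is illustrative, not any
country's reimbursement data.

```python
import cadcea as cc

perf = cc.TestPerformance()                # Sn 0.88, Sp 0.90, NDx 0.05, ...
cfg  = cc.load_config("configs/synthetic_example.yaml")
s1, s2 = cc.evaluate_strategies(0.5, perf, cfg.cost_schedule, cfg.link)
print(s1.expected_cost, s1.ce_ratio, s2.ce_ratio)
# 2121.5107342544334 4788.963282741384 4610.0
print(cc.find_ce_crossing(perf, cfg.cost_schedule, cfg.link))
# CrossingResult(status='found', p_star=0.4298382866610647,
#                ce_at_crossing=5264.544928220828, bracket=(0.429, 0.43))
```

At 50% prevalence the CMR-first strategy costs 2121.51 per patient tested and
4788.96 per correct diagnosis versus 4610.00 for the invasive strategy; the
two strategies are equally cost-effective at a pre-test likelihood of about
43%, below which the CMR-first work-up buys a correct diagnosis more cheaply.

The same analyses run from the shell:

```
cadcea crossing   --config configs/synthetic_example.yaml --out-dir out
cadcea sensitivity --config configs/synthetic_example.yaml \
    --scenario-file configs/sensitivity_scenarios_example.yaml --out-dir out
cadcea microsim   --config configs/synthetic_example.yaml \
    --strategy 1 --p-isch 0.5 --n 200000 --seed 7 --out-dir out
```

Every run writes delimited tables plus a `run_metadata.json` with the config
digest, the parameters in effect and the seed, so outputs are reproducible.

To analyse a real health-care system, transcribe its payer fees into a config
(set `provenance_note` accordingly); per-country replication additionally
expects `configs/country_costs_transcribed.yaml`.

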