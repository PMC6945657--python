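# linactune

Gamma-index driven fine-tuning of linac photon-beam parameters, on
synthetic Monte-Carlo-like dose grids.

## The problem

Commissioning a Monte-Carlo model of a medical linear accelerator means
finding the four parameters of the initial electron beam — energy E0,
energy-spread FWHM, focal-spot FWHM and divergence — that make the
simulated dose in a water phantom match measured percent-depth-dose (PDD)
curves and lateral profiles. Brute-force search at high statistics takes
weeks. The workflow implemented here truncates it using the gamma index

    Gamma(p) = min_i sqrt( (dd_i / dD)^2 + (ds_i / dS)^2 ),   pass if Gamma <= 1,

the standard combined dose-difference (dD) / distance-to-agreement (dS)
metric of radiotherapy dose QA, evaluated at 3%/3mm, 2%/2mm and 1%/1mm:

1. **Energy by trend.** Simulate each candidate E0 at an increasing
   ladder of history counts and correlate the average dose uncertainty
   with the 1%/1mm PDD passing rate. The matching energy shows a strongly
   negative Pearson r (rates climb as noise falls) and clears an 80%
   final rate; a mismatched energy plateaus low — more statistics cannot
   fix a shape error. Decision: r <= -0.80 and final rate >= 80%.
2. **Profiles serially.** With E0 fixed, optimize energy FWHM, then focal
   spot, then divergence — one low-statistics grid search per parameter,
   each stage keeping the 1%/1mm argmax against the measured profiles,
   with an optional cross-depth safeguard that can overturn a stage-1
   pick that wins only at its best depth.

The package is aimed at medical physicists and methodologists who want to
study, test or extend these decision rules without a radiation-transport
code: a parametric dose simulator emulates beam-parameter-dependent
PDD/profile shapes with per-voxel noise falling as 1/sqrt(histories), and
the published commissioning tables for a Varian Clinac 2100 (6 and 10 MV)
ship as exact fixtures.

## Worked example

```python
from linactune import (BeamConfig, generate_reference_scans, select_energy)
from linactune.tuning import Simulator, run_energy_sweep, run_staged_tuning

sim = Simulator()                      # default phantom + model constants
truth = BeamConfig(6.26, energy_fwhm=0.15, focal_spot_fwhm=0.10, divergence=0.0)
golden = generate_reference_scans(truth, nominal_label="6MV-like")

# 1. which initial energy reproduces the golden PDD?
trends = run_energy_sweep(sim, golden.pdd, [6.26, 5.32], master_seed=0)
for t in trends:
    print(f"{t.candidate_label}: r={t.pearson_r:+.2f} final={t.final_rate_1_1:.1f}%")
print("selected:", select_energy(trends).chosen_label)

# 2. recover the remaining parameters in three serial stages
out = run_staged_tuning(sim, golden, 6.26, grids={
    "energy_fwhm": [0.05, 0.10, 0.15, 0.20],
    "focal_spot_fwhm": [0.0, 0.1, 0.2, 0.3],
    "divergence": [0.0, 1.0, 2.0, 3.0]}, master_seed=0)
fc = out.final_config
print(f"tuned: FWHM={fc.energy_fwhm} MeV, spot={fc.focal_spot_fwhm} cm, "
      f"div={fc.divergence} deg")
```

prints

```
6.26 MeV: r=-0.94 final=87.1%
5.32 MeV: r=-0.19 final=3.7%
selected: 6.26 MeV
tuned: FWHM=0.15 MeV, spot=0.1 cm, div=0.0 deg
```

The matched energy's passing rate climbs with statistics (r = -0.94,
final rate above the 80% bar) while the 15%-low candidate saturates near
4% with no usable trend — the rule picks 6.26 MeV; the serial stages then
recover the generating energy FWHM, focal spot and divergence exactly.

A CLI wraps the same functionality: `linactune simulate`, `linactune
gamma`, `linactune tune-energy`, `linactune tune-profiles`, and
`linactune reproduce-tables`, which re-derives every published decision
outcome from the bundled tables (four Pearson r values, both energy
selections, six stage argmax picks, the 4-of-5 cross-depth count) and
prints a pass/fail line for each.

The numbered scripts under `analysis/` run the full studies and write
their tables to `results/`: `01_reproduce_published_decisions.py`
(fixtures only, deterministic), `02_energy_trend_study.py` (trend rule
over 10 seeds), `03_staged_recovery_study.py` (parameter recovery,
including the divergence/energy-FWHM confound that motivates the
cross-depth safeguard).

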