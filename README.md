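# acdose

Quantitative SPECT dosimetry and daughter-specific pharmacokinetics for
²²⁵Ac targeted alpha therapy.

## The problem

[²²⁵Ac]Ac-PSMA ligand therapy for metastatic castration-resistant prostate
cancer injects only ~8 MBq, so post-therapy imaging must rely on the gamma
emissions of two ²²⁵Ac daughters: ²²¹Fr (218 keV, T½ = 4.8 min) and ²¹³Bi
(440 keV, T½ = 45.6 min). Because the first alpha decay's recoil breaks the
chemical bond to the targeting ligand, the longer-lived ²¹³Bi can migrate
away from the ²²⁵Ac decay site before it decays — so the two daughters may
trace *different* pharmacokinetics, and a dosimetry scheme has to decide
which daughter's time-activity curve represents which part of the decay
chain. `acdose` implements the full analysis for such a study:

* **Decay-chain physics** (`acdose.chain`) — chain constants from a packaged
  table, branching-weighted alpha energies (Fr segment 19.2 MeV, Bi segment
  8.345 MeV per head decay), and the two-member Bateman solution for ²¹³Bi
  ingrowth from ²²⁵Ac:

  A_Bi(t) = A_Ac(0)·λ_Bi/(λ_Bi−λ_Ac)·(e^(−λ_Ac t) − e^(−λ_Bi t)) + A_Bi(0)·e^(−λ_Bi t)

* **Image quantification** (`acdose.imaging`) — phantom-based calibration of
  cps/voxel volumes to Bq/ml, 30-mm-FWHM Gaussian post-filtering, 80 %
  isocontour lesion segmentation, and SUV extraction
  (SUV = C / (A_inj/body mass), density 1 g/ml, no recovery correction).

* **Kinetics** (`acdose.kinetics`) — mono-exponential time-activity fits
  A(t) = A(t₀)·e^(−ln2·t/T_eff), exact closed form for the two-scan case,
  decomposition 1/T_eff = 1/T_phys + 1/T_bio, and time-integrated activity
  Ã = A(t₀)·T_eff/ln2.

* **Dosimetry** (`acdose.dosimetry`) — MIRD self-dose D = Ã·S with RBE
  weighting (default 5), under three chain partitions: the whole chain on
  the ²¹³Bi TAC (method 1), on the ²²¹Fr TAC (method 2), or split at ²¹³Bi
  with both TACs combined (method 3).

* **Urine analysis** (`acdose.urine`) — bound-constrained Bateman fits of
  gamma-counter series recovering A_Ac(0) and A_Bi(0) per sample, and cohort
  Bi/Ac-ratio summaries.

* **Statistics** (`acdose.stats`) — Pearson correlation with t-transform
  p-values and an *exact* Wilcoxon signed-rank test (full enumeration of the
  2ⁿ sign assignments for n ≤ 25).

* **Synthetic data** (`acdose.synth`) — seeded generators for every input:
  voxel phantoms with organ kinetics, Poisson counting noise, TAC and urine
  series, so the whole pipeline is testable without patient data.

* **Workflow** (`acdose.workflow`, CLI `acdose`) — orchestration from a study
  config to the report tables (SUVs, half-lives, doses, urine ratios,
  statistics) plus a run log.

## Worked example

`examples/` holds one short script per capability. Urine analysis on the
packaged five-patient reference cohort (`python examples/urine_bateman_fit.py`):

```
patient    epoch (h)   Ac-225   Bi-213  ratio
patient_1       17.0    242.6    218.9   0.90
...
patient_5       42.0    113.2    115.6   1.02

mean ratio, epoch 1: 0.98 +/- 0.15 (population SD)
mean ratio, epoch 2: 1.08 +/- 0.09
mean change: +10 +/- 9 percentage points
```

The Bi/Ac ratio in urine rises by ~10 percentage points between ~24 h and
~48 h after injection: relatively more free ²¹³Bi is excreted late, the
signature of a daughter no longer bound to the ligand. Dosimetry for a
247-ml kidney (`python examples/kidney_lesion_dosimetry.py`):

```
method 1 (Bi-213 TAC): 0.351 Gy, 1.754 Sv_RBE, 0.228 Sv_RBE/MBq
method 2 (Fr-221 TAC): 0.312 Gy, 1.559 Sv_RBE, 0.202 Sv_RBE/MBq
method 3 (combined): 0.324 Gy, 1.618 Sv_RBE, 0.210 Sv_RBE/MBq

method 1 vs 2:  11.8% (symmetric)
```

With a 27 h ²¹³Bi and 24 h ²²¹Fr effective half-life the three partitioning
choices differ by ≲ 12 % — the daughter-specific kinetics shifts the dose
estimate only mildly. A full synthetic study (simulate → calibrate →
quantify → fit → dose → stats) runs with
`python examples/synthetic_study.py`, or from the shell:

```
acdose simulate --seed 7 --n-patients 2 --outdir inputs/
acdose run-all --config inputs/study_config.json --root inputs/ --outdir report/
```

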