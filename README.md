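# prestim

Prestimulus-oscillation analysis for the **visual rabbit illusion**: does the
phase and power of alpha-band (8–12 Hz) brain activity *before* an ambiguous
three-flash sequence predict whether an observer reports the illusory
(intermediate) position of the second flash?

The package is aimed at electrophysiology researchers who want a tested,
seed-reproducible implementation of this analysis chain — and at
methodologists who want to study its statistical behavior on synthetic data,
since no public recordings exist for the paradigm.

## What it implements

* **Behavioral layer** — trial labeling (ILL / no-ILL / control-correct), RT
  filtering, illusion rates, and the signal-detection criterion
  `c = −(z(H) + z(FA))/2` with an adapted confusion matrix (H = control
  trials correctly perceived, FA = test trials reported illusory).
* **Spectral layer** — single-trial Morlet decomposition with a *fixed 3 Hz
  spectral bandwidth* (bandwidth = 2× spectral SD, so `n_cycles = 2f/3`:
  3.7 cycles at 5.5 Hz, 6.7 at 10 Hz), band power and intertrial phase
  coherence (ITC), Euclidean-norm planar combination, prestimulus
  restriction (−600…−200 ms), amplitude-based epoch rejection, and
  trial-count equalization.
* **Phase opposition sum** — `POS = ITC_ILL + ITC_no-ILL − 2·ITC_all` with a
  two-level permutation null (label shuffles per subject, n=1000; one draw
  per subject averaged at the group level, n=10,000) and z-scoring against
  the group null.
* **Cluster-permutation inference** — spatiotemporal clustering for POS maps
  (per-point percentile thresholds, minimal cluster size 10, max-cluster-sum
  correction), for between-subject Spearman correlation maps (t-transform
  forming threshold 0.01 two-sided, minimum 2 spatial neighbors, subject
  shuffles, 4000 permutations), a conjunction analysis across sequence
  directions (signed min-|r|, max-over-cluster statistic), a paired
  sign-flip power contrast, percentile-bootstrap CIs, Rayleigh test, and
  circular means.
* **Synthetic data** — full study designs (5 blocks; 900 trials; SOA 188 ms
  inward / 272 ms outward; epochs −0.8…+1.2 s at 333 Hz), a logistic
  response model with injectable phase- and power-coupling effects, raw
  epochs (1/f noise + alpha oscillators + evoked transients), and a fast
  band-level cohort generator for statistical validation.

See `docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a 13-subject cohort with a phase-opposition effect injected at five
sensors of the default 8×8 grid, then run the group analysis:

```python
from prestim.synth import simulate_latent_cohort
from prestim.pipeline import AnalysisConfig, run_cohort_analysis, report_to_markdown

cohort = simulate_latent_cohort(
    n_subjects=13, seed=7, phase_coupling=2.0,
    effect_sensors=[19, 27, 28, 35, 36],
)
config = AnalysisConfig(n_subject_perm=200, n_group_perm=1000)
for c in (config.corr_cluster, config.contrast_cluster, config.conjunction_cluster):
    c.n_permutations = 200
report, _ = run_cohort_analysis(cohort, config, seed=1)
print(report_to_markdown(report))
```

Output:

```
# Prestimulus analysis report

## Phase opposition (POS), pooled directions
- clusters: 5 (1 significant); max z = 66.97
  - T_sum = 391.71, 804 points, p = 0.0010
## ILL vs no-ILL power contrast (pooled)
- clusters: 81 (0 significant)
## Between-subject correlations
- illusion_rate_inward: 0 clusters, 0 significant
- criterion_inward: 0 clusters, 0 significant
- illusion_rate_outward: 0 clusters, 0 significant
- criterion_outward: 0 clusters, 0 significant
## Conjunction across directions: 0 significant clusters
```

Reading this: the POS cluster test recovers the injected phase effect — one
significant cluster (`T_sum` = summed POS over its 804 sensor–time points,
p = 0.001 against the max-cluster-statistic null of 1000 group-null draws,
peak z ≈ 67 against the group null), while the power-based arms produce only
sub-threshold clusters, as they should when only a phase effect is injected. With
`phase_coupling=0.0` and `power_bias_coupling=0.0` all arms are null; with
only a power×bias coupling the correlation arm lights up instead.

A command-line interface mirrors this flow on raw simulated epochs:

```bash
prestim simulate --subjects 6 --seed 1 --grid 4 --out data/
prestim run --data data/ --out report.json
prestim cycles --freq 10        # -> 6.7
```

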