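# Methods

`prestim` re-implements, as a tested and reusable pipeline, the prestimulus
oscillation analysis used to study the visual rabbit illusion: does the phase
and power of alpha-band (8–12 Hz) activity *before* an ambiguous three-flash
sequence predict whether the observer will report the illusory (intermediate)
position of the second flash?

No public recordings exist for this paradigm, so the package pairs the
analysis chain with a synthetic-data generator that injects known
ground-truth effects. Everything below is the package's own account of its
models and choices.

## Paradigm and behavioral layer

A session has 5 blocks; each block presents, per motion direction (inward,
SOA 188 ms; outward, SOA 272 ms), 60 *test* sequences (second flash at the
first flash's position; may be mislocalized) and 30 *control* sequences
(second flash truly intermediate). Totals per subject: 900 trials, 600 test
(300 per direction), 300 control. Inter-trial intervals are uniform on
0.8–1.3 s.

Trials are labeled from (condition, response): test+intermediate → **ILL**,
test+not-intermediate → **no-ILL**, control trials are correct when reported
intermediate; incorrect control trials are flagged excluded. RTs outside
[0.2 s, 4 s] are rejected (bounds are parameters; the single RT column is
measured from last-flash onset — the alternative origin at second-flash
offset mentioned in some descriptions of this paradigm is handled by simply
passing different bounds).

The response-bias criterion uses an adapted confusion matrix — hit rate H =
proportion of control trials correctly perceived, false-alarm rate FA =
proportion of test trials reported illusory —

    c = −(z(H) + z(FA)) / 2 .

Numerics: z is implemented as the symmetrized normal quantile
(ndtri(p) − ndtri(1−p))/2, and complementary rates (H + FA within one ulp of
1) short-circuit to c = 0, so the identity c(H, 1−H) = 0 holds exactly in
floating point. Degenerate rates (0 or 1) are replaced by 1/(2N) resp. 1 − 1/(2N)
when the trial count N is available ("half-count" rule); a log-linear
(add-0.5) correction is a reasonable alternative but is not implemented.

## Spectral layer

Time–frequency decomposition uses Morlet wavelets with a *fixed spectral
bandwidth* of 3 Hz, defining bandwidth as twice the spectral SD of the
kernel, so the cycle count grows linearly with frequency:

    n_cycles(f) = 2 f / bandwidth    (e.g. 3.7 @ 5.5 Hz, 6.7 @ 10 Hz, 53.3 @ 80 Hz).

The transform itself is delegated to `mne.time_frequency.tfr_array_morlet`
(complex output, zero-mean kernels); frequencies whose kernel (±5 temporal
SDs) exceeds the epoch raise an error naming the frequency. Band power and
ITC are arithmetic means over integer center frequencies inside the band,
edges inclusive (alpha 8–12, theta 4–7, beta 13–30, low-gamma 30–45,
high-gamma 60–100 Hz). No baseline normalization is applied anywhere; all
predictors are read from the prestimulus window −600…−200 ms, whose
endpoints are snapped to the nearest samples (134 samples at 333 Hz).
Orthogonal planar-gradiometer pairs are combined per site by the Euclidean
norm — applied to band power before subject averaging, and to POS maps
before clustering. ILL/no-ILL trial counts are equalized per
response × direction cell by seeded random subsampling to the minimum cell
count.

## Phase opposition

For single-trial phases, ITC is the length of the mean unit phasor across
trials. The phase opposition sum

    POS = ITC_ILL + ITC_no-ILL − 2·ITC_all

is ≈ 0 when both conditions share one phase distribution and → 2 when the
two conditions lock to opposite phases (pooled phasors cancel). ITCs are
computed per wavelet center frequency and band-averaged before forming POS.
Note POS is positively biased at finite n (E[POS] = 2E[R̄_n] − 2E[R̄_2n] > 0
under uniformity); inference therefore never compares POS to zero but to its
permutation null.

Two-level null: per subject, ILL/no-ILL labels are shuffled (preserving
counts) and POS recomputed over all sensors and time points (default
n = 1000); at the group level one subject-level sample per individual is
drawn (with replacement — the default group size n = 10,000 exceeds the
per-subject 1000) and averaged. The observed group POS is z-scored against
the group-null mean/SD pointwise. The permutation engine computes all
shuffles in one indicator-matrix product with the per-trial phasors, in
float32; tests verify it against a float64 per-permutation oracle.

## Cluster inference

Supra-threshold sensor–time points are clustered under spatial (sensor
adjacency) + temporal (consecutive samples) connectivity; positive and
negative points cluster separately; family-wise correction compares each
observed cluster statistic to the permutation distribution of the maximum
|cluster statistic|; p = (count ≥ observed + 1)/(n_perm + 1).

* **POS test** — pointwise thresholds are the 2.5/97.5 percentiles of the
  group null per sensor–time point (per-point rather than pooled; this is a
  package choice where the procedure could be read either way); clusters
  need ≥ 10 points; the cluster statistic is the sum of POS.
* **Power–behavior correlation** — pointwise Spearman r (average-rank ties)
  between per-subject ILL−no-ILL prestimulus alpha-power maps and a
  behavioral scalar (illusion rate or criterion), t-transformed
  (t = r√((n−2)/(1−r²))); clusters form at the two-sided 0.01 Student-t
  quantile and members must keep ≥ 2 supra-threshold spatial neighbors at
  the same sample (no cluster-size floor); the null shuffles the subjects of
  the behavioral vector (default 4000 permutations). Analyses run per
  direction because the behavioral measures are direction specific.
* **Conjunction across directions** — pointwise signed min(|r_in|, |r_out|),
  set to 0 where the signs disagree (the magnitude rule is standard; the
  sign rule is a package choice). The null re-shuffles each direction's
  behavioral vector independently; pointwise thresholds are the two-sided
  0.01 percentiles of the null conjunction values; the cluster statistic is
  the *maximum* over the cluster.
* **ILL vs no-ILL power contrast** — pooled directions, paired difference
  maps, one-sample t across subjects as forming statistic (two-sided 0.01),
  null by subject-level sign flipping.

Percentile-bootstrap 95% CIs for Spearman correlations resample subjects
with replacement (default 2000 draws); resamples with a constant vector are
skipped and counted. Circular helpers: Rayleigh Z = nR̄² with the standard
small-sample p approximation exp(√(1+4n+4(n²−R²)) − (1+2n)), and the phasor
mean direction.

## Synthetic data

**Raw epochs** (`simulate_epochs`): −0.8…+1.2 s at 333 Hz (generated
directly at the post-downsampling rate; no filter/decimation chain), each
epoch = unit-variance 1/f-shaped Gaussian noise (spectral exponent 1 by
default) + an alpha oscillator (10 Hz) at designated effect sensors with
trial-random phase and log-normal amplitude + small Gaussian-windowed
evoked-like transients ~100 ms after each flash. The injected per-trial
phase (at −400 ms) and squared amplitude are returned so behavior can couple
to them. The default layout is an 8×8 grid with rook adjacency — the
smallest structure that meaningfully exercises spatial clustering; a
planar-pair mode duplicates each site into two orthogonal channels.

**Response model**: test trials report "intermediate" with probability

    sigmoid( logit(base) + w_pow · sign(base − ½) · z_power + w_phase · cos(φ − φ_pref) )

with z_power standardized within subject; control trials are correct with
fixed accuracy 0.81 (mirroring observed control performance); RTs are
log-normal (median 0.55 s control / 0.68 s test, σ = 0.35, reproducing the
~130 ms control advantage). Per-subject base rates are uniform on
0.12–0.95, the observed between-subject range. With both couplings at zero
every downstream statistic is exercised under an exact null. The paradigm's
generative link between alpha and perception is unknown; this logistic model
is an artifact choice, not a claim about mechanism.

**Latent-level cohorts** (`simulate_latent_cohort`): for large statistical
validations the raw-signal + wavelet stage is bypassed and the generator
emits directly the band-level prestimulus phase/power arrays the spectral
chain would produce: every channel carries an alpha oscillator with
trial-random phase offset advancing at 10 Hz across the 134-sample window;
at effect sensors the offset is the response-coupled phase plus
wrapped-normal jitter (σ = 0.3), and the power field is unit Gaussian noise
plus the response-coupled latent. The full behavioral session (design,
logistic responses, labeling, RT draw, equalization) is simulated with the
same code as the raw path. What this deliberately does *not* emulate:
spatially correlated background fields, temporal autocorrelation of power,
1/f spectral leakage into the band, artifacts. Passing tests therefore
demonstrate correctness and calibration of the statistics under exchangeable
nulls and detectability of localized effects — not robustness to every
property of real MEG data.

## Validation conditions

The acceptance suite runs, per the package's standard conditions: 100 null
cohorts (13 subjects, 64 sensors, 134 time points; reduced permutations 200
subject-level / 1000 group-level / 200 cluster) for family-wise error
(bound 0.10 around the nominal 0.05 union of one POS and one correlation
test); 25 cohorts each for effect recovery (≥ 80% hit rate). Injected
conditions, frozen once by Monte-Carlo calibration: phase arm
w_phase = 2.0 on 5 sensors; power arm w_pow = 0.5 on a 3×3 patch with a
shared base rate across directions, which realizes a true between-subject
Spearman ρ ≈ 0.8 between the patch power difference and the illusion rate
(independently drawn per-direction rates cap the achievable correlation
near 0.65 because the coupling magnitude is a subject-level constant).
Rank-uniformity of cluster p-values is verified by treating one null draw
as observed among its peers (exact exchangeability) over 200 repeats.

## Known limitations

* The latent cohort generator injects time-constant effects over the
  prestimulus window; temporal localization of clusters is exercised only
  structurally, not calibrated against drifting effects.
* The correlation cluster test with 13 subjects has coarse permutation
  resolution (13! is large but rank statistics at n = 13 are granular);
  p-values below ~1/n_perm are reported at the add-one floor.
* Planar-pair simulation duplicates one signal per site rather than
  modelling orthogonal field derivatives.
* The "35 cycles at 37.5 Hz" sometimes quoted for fixed-3-Hz-bandwidth
  Morlet families is inconsistent with the linear rule (which gives 25);
  the package implements the rule, which reproduces the other published
  cycle counts.
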