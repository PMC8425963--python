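"""Synthetic cohorts for the three-flash (rabbit illusion) paradigm.

The generator mirrors the study design: five blocks per session, each with 60
test and 30 control trials per motion direction (inward SOA 188 ms, outward
272 ms), i.e. 900 trials per subject of which 600 are test trials.  Epochs run
from -0.8 s to +1.2 s around the onset of the first flash at 333 Hz.

Two levels of simulation are provided:

* :func:`simulate_epochs` builds raw multi-sensor time series (1/f background
  noise + an alpha-band oscillator at designated effect sensors + evoked-like
  transients) and records the injected per-trial alpha phase and power so the
  behavioral model can couple perception to them.
* :func:`simulate_latent_cohort` skips the raw time series and emits the
  band-level phase/power arrays a wavelet analysis would produce over the
  prestimulus window.  This is the workhorse for large statistical
  validations (type-I error, effect recovery) where simulating and
  transforming raw epochs for hundreds of cohorts would add nothing but cost.

Ground truth is injected through two per-subject couplings entering a
logistic response model for test trials:

``p(ILL) = sigmoid(logit(base) + w_pow * sign(base - 0.5) * z_power
          + w_phase * cos(phase - preferred_phase))``

With both couplings at zero every downstream statistic is exercised under a
true null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .containers import EpochSet

__all__ = [
    "StudyDesign",
    "SubjectProfile",
    "SensorLayout",
    "TrialLatent",
    "SubjectLatent",
    "Cohort",
    "grid_layout",
    "generate_design",
    "simulate_responses",
    "simulate_epochs",
    "simulate_subject",
    "simulate_latent_cohort",
]


@dataclass
class StudyDesign:
    """Session structure.  Defaults reproduce the study protocol."""

    n_blocks: int = 5
    test_per_block_per_direction: int = 60
    control_per_block_per_direction: int = 30
    directions: tuple = ("inward", "outward")
    soa: dict = field(default_factory=lambda: {"inward": 0.188, "outward": 0.272})
    iti_range: tuple = (0.8, 1.3)
    epoch_window: tuple = (-0.8, 1.2)
    sampling_rate: float = 333.0

    def validate(self) -> None:
        if self.n_blocks <= 0:
            raise ValueError("n_blocks must be positive")
        if self.test_per_block_per_direction <= 0 or self.control_per_block_per_direction <= 0:
            raise ValueError("per-block trial counts must be positive")
        if not self.iti_range[0] < self.iti_range[1]:
            raise ValueError("iti_range must satisfy low < high")
        if not (self.epoch_window[0] < 0.0 < self.epoch_window[1]):
            raise ValueError("epoch_window must straddle first-flash onset")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        for d in self.directions:
            if d not in self.soa:
                raise ValueError(f"missing SOA for direction {d!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)

    @classmethod
    def from_json(cls, path) -> "StudyDesign":
        with open(path) as f:
            d = json.load(f)
        d["directions"] = tuple(d["directions"])
        d["iti_range"] = tuple(d["iti_range"])
        d["epoch_window"] = tuple(d["epoch_window"])
        return cls(**d)


@dataclass
class SubjectProfile:
    """Per-subject generative parameters.

    ``base_illusion_rate`` may be a scalar (shared across directions) or a
    ``{direction: rate}`` mapping.  ``power_bias_coupling`` and
    ``phase_coupling`` are the dimensionless weights of the two injected
    effects; zero disables them.
    """

    subject_id: str = "S00"
    base_illusion_rate: object = 0.5
    power_bias_coupling: float = 0.0
    phase_coupling: float = 0.0
    preferred_phase: float = 0.0
    alpha_amplitude: float = 1.0
    noise_exponent: float = 1.0
    control_accuracy: float = 0.81

    def rate_for(self, direction: str) -> float:
        if isinstance(self.base_illusion_rate, dict):
            r = float(self.base_illusion_rate[direction])
        else:
            r = float(self.base_illusion_rate)
        if not 0.0 < r < 1.0:
            raise ValueError("base_illusion_rate must lie in (0, 1)")
        return r

    def validate(self) -> None:
        for d in ("inward", "outward"):
            if isinstance(self.base_illusion_rate, dict) and d not in self.base_illusion_rate:
                continue
            self.rate_for(d)
        if self.alpha_amplitude < 0:
            raise ValueError("alpha_amplitude must be >= 0")
        if not 0.0 < self.control_accuracy <= 1.0:
            raise ValueError("control_accuracy must lie in (0, 1]")


@dataclass
class SensorLayout:
    """2D sensor array with a symmetric, irreflexive adjacency.

    ``channel_kind='planar_pair'`` doubles each site into two orthogonal
    channels (suffix ``_a`` / ``_b``); adjacency and positions are defined on
    sites, and ``site_of_channel`` maps channels back to sites.
    """

    sensor_ids: list
    positions: np.ndarray
    adjacency: np.ndarray
    channel_kind: str = "single"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        n = len(self.sensor_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square over sites")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("adjacency must be irreflexive")
        if n > 1 and np.any(self.adjacency.sum(axis=1) == 0):
            raise ValueError("every site needs at least one neighbor")
        if self.channel_kind not in ("single", "planar_pair"):
            raise ValueError("channel_kind must be 'single' or 'planar_pair'")

    @property
    def n_sites(self) -> int:
        return len(self.sensor_ids)

    @property
    def n_channels(self) -> int:
        return self.n_sites * (2 if self.channel_kind == "planar_pair" else 1)

    @property
    def channel_ids(self) -> list:
        if self.channel_kind == "single":
            return list(self.sensor_ids)
        out = []
        for s in self.sensor_ids:
            out += [f"{s}_a", f"{s}_b"]
        return out

    @property
    def site_of_channel(self) -> np.ndarray:
        if self.channel_kind == "single":
            return np.arange(self.n_sites)
        return np.repeat(np.arange(self.n_sites), 2)

    def to_json(self, path) -> None:
        i, j = np.nonzero(np.triu(self.adjacency))
        with open(path, "w") as f:
            json.dump(
                {
                    "sensor_ids": list(self.sensor_ids),
                    "positions": self.positions.tolist(),
                    "edges": np.stack([i, j], axis=1).tolist(),
                    "channel_kind": self.channel_kind,
                },
                f,
            )

    @classmethod
    def from_json(cls, path) -> "SensorLayout":
        with open(path) as f:
            d = json.load(f)
        n = len(d["sensor_ids"])
        adj = np.zeros((n, n), dtype=bool)
        for i, j in d["edges"]:
            adj[i, j] = adj[j, i] = True
        return cls(d["sensor_ids"], np.asarray(d["positions"]), adj, d["channel_kind"])


def grid_layout(n_rows: int = 8, n_cols: int = 8, channel_kind: str = "single") -> SensorLayout:
    """Rectangular grid with 4-neighbour (rook) adjacency.

    The default 8 x 8 grid is the smallest structure that meaningfully
    exercises spatial clustering while standing in for the 102-site sensor
    array of a whole-head system.
    """
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    pos = np.stack([cc.ravel(), rr.ravel()], axis=1).astype(float)
    n = n_rows * n_cols
    adj = np.zeros((n, n), dtype=bool)
    idx = lambda r, c: r * n_cols + c  # noqa: E731
    for r in range(n_rows):
        for c in range(n_cols):
            if c + 1 < n_cols:
                adj[idx(r, c), idx(r, c + 1)] = adj[idx(r, c + 1), idx(r, c)] = True
            if r + 1 < n_rows:
                adj[idx(r, c), idx(r + 1, c)] = adj[idx(r + 1, c), idx(r, c)] = True
    ids = [f"S{i:03d}" for i in range(n)]
    return SensorLayout(ids, pos, adj, channel_kind)


# ---------------------------------------------------------------------------
# design / responses


def generate_design(design: StudyDesign, seed: int) -> pd.DataFrame:
    """Build the per-block randomized trial list (responses unset).

    Counts per block x condition x direction are exact; order is shuffled
    within block; ITIs are drawn uniformly from ``design.iti_range``.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for block in range(design.n_blocks):
        block_rows = []
        for direction in design.directions:
            block_rows += [("test", direction)] * design.test_per_block_per_direction
            block_rows += [("control", direction)] * design.control_per_block_per_direction
        order = rng.permutation(len(block_rows))
        for k in order:
            cond, direction = block_rows[k]
            rows.append(
                {
                    "block": block,
                    "condition": cond,
                    "direction": direction,
                    "soa": design.soa[direction],
                    "iti": rng.uniform(*design.iti_range),
                }
            )
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(len(df)))
    df["response"] = pd.NA
    df["rt"] = np.nan
    return df


@dataclass
class TrialLatent:
    """Injected per-trial oscillatory state at the effect sensors.

    ``phase`` is the alpha phase (radians) at ``ref_time`` (mid-prestimulus by
    default); ``power`` is the squared alpha amplitude (or, for the latent
    cohort generator, the standardized band power).
    """

    phase: np.ndarray
    power: np.ndarray
    ref_time: float = -0.4
    effect_sensors: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __len__(self):
        return len(self.phase)


def simulate_responses(
    trials: pd.DataFrame,
    profile: SubjectProfile,
    latent: TrialLatent,
    seed: int,
    rt_median: dict | None = None,
    rt_sigma: float = 0.35,
) -> pd.DataFrame:
    """Draw responses and RTs from the logistic perception model.

    Test trials report "intermediate" with probability
    ``sigmoid(logit(base) + w_pow*sign(base-0.5)*z_power + w_phase*cos(phase - preferred))``
    where ``z_power`` is the latent power standardized over test trials within
    the subject.  Control trials are correct ("intermediate") with fixed
    accuracy.  RTs are log-normal with a condition-specific median.
    """
    profile.validate()
    if latent is None or len(latent) != len(trials):
        raise ValueError("latent values must align one-to-one with trials")
    rng = np.random.default_rng(seed)
    if rt_median is None:
        rt_median = {"test": 0.68, "control": 0.55}

    out = trials.copy()
    is_test = (out["condition"] == "test").to_numpy()

    base = np.array([profile.rate_for(d) for d in out["direction"]])
    bias_sign = np.sign(base - 0.5)

    power = np.asarray(latent.power, dtype=float)
    tp = power[is_test]
    zpow = np.zeros_like(power)
    if is_test.any() and np.std(tp) > 0:
        zpow[is_test] = (tp - tp.mean()) / tp.std()

    eta = logit(base)
    eta = eta + profile.power_bias_coupling * bias_sign * zpow
    eta = eta + profile.phase_coupling * np.cos(np.asarray(latent.phase) - profile.preferred_phase)
    p_ill = expit(eta)

    u = rng.random(len(out))
    resp = np.where(u < p_ill, "intermediate", "not-intermediate")
    # control trials: correct (= "intermediate") with fixed accuracy
    ctrl = ~is_test
    resp[ctrl] = np.where(
        rng.random(ctrl.sum()) < profile.control_accuracy, "intermediate", "not-intermediate"
    )
    out["response"] = resp

    med = np.where(is_test, rt_median["test"], rt_median["control"])
    out["rt"] = np.exp(np.log(med) + rt_sigma * rng.standard_normal(len(out)))
    return out


# ---------------------------------------------------------------------------
# raw epochs


def _epoch_times(window, fs):
    k0 = int(round(window[0] * fs))
    k1 = int(round(window[1] * fs))
    return np.arange(k0, k1 + 1) / fs


def _one_over_f_noise(rng, shape, n_times, fs, exponent):
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit variance."""
    freqs = np.fft.rfftfreq(n_times, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape + (len(freqs),)) + 1j * rng.standard_normal(shape + (len(freqs),))) * gain
    x = np.fft.irfft(spec, n=n_times, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def simulate_epochs(
    trials: pd.DataFrame,
    profile: SubjectProfile,
    layout: SensorLayout,
    design: StudyDesign,
    seed: int,
    effect_sensors=None,
    f_alpha: float = 10.0,
    noise_amplitude: float = 1.0,
    evoked_amplitude: float = 0.5,
    amplitude_sigma: float = 0.3,
    ref_time: float = -0.4,
):
    """Generate raw epochs plus the latent record of injected phase/power.

    Each epoch is 1/f-coloured background noise plus, at the effect sensors,
    an alpha oscillator with trial-random phase and log-normal amplitude, plus
    small evoked-like transients after each flash onset.  The returned
    :class:`TrialLatent` carries the alpha phase at ``ref_time`` and the
    squared amplitude, which :func:`simulate_responses` couples to behavior.
    Fully reproducible given the seed.
    """
    design.validate()
    w0, w1 = design.epoch_window
    if (w1 - w0) < 1.0 / f_alpha:
        raise ValueError("epoch window shorter than one alpha cycle")
    rng = np.random.default_rng(seed)
    times = _epoch_times(design.epoch_window, design.sampling_rate)
    n_trials, n_chan, n_times = len(trials), layout.n_channels, len(times)

    if effect_sensors is None:
        # central patch of the site grid by default
        effect_sensors = np.arange(layout.n_sites)[: max(1, layout.n_sites // 16)]
    effect_sensors = np.asarray(effect_sensors, dtype=int)
    site_of = layout.site_of_channel
    effect_channels = np.flatnonzero(np.isin(site_of, effect_sensors))

    data = noise_amplitude * _one_over_f_noise(
        rng, (n_trials, n_chan), n_times, design.sampling_rate, profile.noise_exponent
    )

    phi = rng.uniform(-np.pi, np.pi, size=n_trials)
    amp = profile.alpha_amplitude * np.exp(amplitude_sigma * rng.standard_normal(n_trials))
    osc = amp[:, None] * np.cos(2 * np.pi * f_alpha * times[None, :] + phi[:, None])
    for ch in effect_channels:
        data[:, ch, :] += osc

    # evoked-like transients ~100 ms after each flash onset, all channels
    soa = trials["soa"].to_numpy(dtype=float)
    for k in range(3):
        onset = k * soa
        t_rel = times[None, :] - (onset[:, None] + 0.10)
        data += (evoked_amplitude * np.exp(-0.5 * (t_rel / 0.02) ** 2))[:, None, :]

    latent = TrialLatent(
        phase=np.angle(np.exp(1j * (2 * np.pi * f_alpha * ref_time + phi))),
        power=amp**2,
        ref_time=ref_time,
        effect_sensors=effect_sensors,
    )
    epochs = EpochSet(
        data=data,
        times=times,
        sampling_rate=design.sampling_rate,
        trial_ids=trials["trial"].to_numpy(),
        subject_id=profile.subject_id,
        sensor_ids=layout.channel_ids,
    )
    return epochs, latent


def simulate_subject(profile, layout, design, seed, **epoch_kwargs):
    """Design + epochs + responses for one subject.  Returns (trials, epochs, latent)."""
    ss = np.random.SeedSequence(seed)
    s_design, s_epochs, s_resp = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    trials = generate_design(design, s_design)
    epochs, latent = simulate_epochs(trials, profile, layout, design, s_epochs, **epoch_kwargs)
    trials = simulate_responses(trials, profile, latent, s_resp)
    return trials, epochs, latent


# ---------------------------------------------------------------------------
# latent-level cohorts


@dataclass
class SubjectLatent:
    """Band-level prestimulus state for the equalized test trials of one subject."""

    subject_id: str
    labels: np.ndarray          # 'ILL' / 'no-ILL' per retained trial
    directions: np.ndarray      # direction per retained trial
    phases: np.ndarray          # (n_trials, n_channels, n_times) float32, radians
    power: np.ndarray           # (n_trials, n_channels, n_times) float32
    behavior: dict              # illusion_rate / criterion per direction and pooled

    def power_diff_map(self, direction=None) -> np.ndarray:
        """Mean prestimulus power, ILL minus no-ILL, per sensor x time."""
        keep = np.ones(len(self.labels), bool) if direction is None else self.directions == direction
        ill = self.power[keep & (self.labels == "ILL")].mean(axis=0)
        noill = self.power[keep & (self.labels == "no-ILL")].mean(axis=0)
        return (ill - noill).astype(np.float64)


@dataclass
class Cohort:
    subjects: list
    layout: SensorLayout
    times: np.ndarray
    effect_sensors: np.ndarray

    def power_diff_maps(self, direction=None) -> np.ndarray:
        return np.stack([s.power_diff_map(direction) for s in self.subjects])

    def behavior_vector(self, measure="illusion_rate", direction=None) -> np.ndarray:
        key = measure if direction is None else f"{measure}_{direction}"
        return np.array([s.behavior[key] for s in self.subjects])


def simulate_latent_cohort(
    n_subjects: int = 13,
    layout: SensorLayout | None = None,
    seed: int = 0,
    design: StudyDesign | None = None,
    base_rate_range: tuple = (0.12, 0.95),
    shared_base_rate: bool = False,
    phase_coupling: float = 0.0,
    power_bias_coupling: float = 0.0,
    scale_power_coupling_by_bias: bool = True,
    effect_sensors=None,
    prestim_window: tuple = (-0.6, -0.2),
    f_alpha: float = 10.0,
    phase_jitter: float = 0.3,
    power_map_noise: float = 1.0,
) -> Cohort:
    """Simulate a cohort at the band-limited latent level.

    Per subject: the full behavioral session is generated (design, logistic
    responses, RTs), trials are labeled and equalized per response x
    direction, and the retained test trials receive prestimulus alpha phase
    and power arrays over ``layout`` channels and the prestimulus time grid.

    Every channel carries an alpha oscillator with trial-random phase; at the
    effect sensors the phase is the one the response model was coupled to
    (plus ``phase_jitter`` wrapped-normal noise) and the power offset is the
    coupled latent.  Elsewhere phase offsets and power are independent noise,
    so with both couplings at zero the cohort is an exact null.
    """
    from .behavior import classify_trials, summarize_behavior
    from .spectral import equalize_trials

    if layout is None:
        layout = grid_layout(8, 8)
    if design is None:
        design = StudyDesign()
    if effect_sensors is None:
        effect_sensors = np.array([27, 28, 35, 36, 19], dtype=int) % layout.n_sites
    effect_sensors = np.unique(np.asarray(effect_sensors, dtype=int))
    site_of = layout.site_of_channel
    effect_channels = np.flatnonzero(np.isin(site_of, effect_sensors))

    fs = design.sampling_rate
    k0 = int(round(prestim_window[0] * fs))
    k1 = int(round(prestim_window[1] * fs))
    times = np.arange(k0, k1 + 1) / fs
    n_chan, n_times = layout.n_channels, len(times)

    ss = np.random.SeedSequence(seed)
    subjects = []
    for si, child in enumerate(ss.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        lo, hi = base_rate_range
        if shared_base_rate:
            b = rng.uniform(lo, hi)
            base = {d: b for d in design.directions}
        else:
            base = {d: rng.uniform(lo, hi) for d in design.directions}
        mean_bias = np.mean([base[d] for d in design.directions]) - 0.5
        w_pow = power_bias_coupling * (abs(2 * mean_bias) if scale_power_coupling_by_bias else 1.0)
        profile = SubjectProfile(
            subject_id=f"S{si:02d}",
            base_illusion_rate=base,
            power_bias_coupling=w_pow,
            phase_coupling=phase_coupling,
            preferred_phase=rng.uniform(-np.pi, np.pi),
        )
        seeds = rng.integers(2**31, size=4)
        trials = generate_design(design, int(seeds[0]))
        n = len(trials)
        # latent: one coupled alpha phase and one coupled (standardized) power per trial
        phi = rng.uniform(-np.pi, np.pi, size=n)
        pow_lat = rng.standard_normal(n)
        latent = TrialLatent(phase=phi, power=pow_lat, effect_sensors=effect_sensors)
        trials = simulate_responses(trials, profile, latent, int(seeds[1]))
        trials = classify_trials(trials)
        behav = summarize_behavior(trials)

        test_mask = trials["label"].isin(["ILL", "no-ILL"]).to_numpy()
        test_idx = np.flatnonzero(test_mask)
        labels = trials.loc[test_mask, "label"].to_numpy()
        dirs = trials.loc[test_mask, "direction"].to_numpy()
        keep_rel = equalize_trials(labels, dirs, seed=int(seeds[2]))
        keep = test_idx[keep_rel]

        nk = len(keep)
        # phase offsets per trial x channel: independent everywhere, coupled at
        # effect channels (wrapped-normal jitter around the latent phase);
        # offsets stay unwrapped -- downstream statistics only use cos/sin
        offsets = rng.uniform(-np.pi, np.pi, size=(nk, n_chan)).astype(np.float32)
        coupled = phi[keep, None] + phase_jitter * rng.standard_normal((nk, len(effect_channels)))
        offsets[:, effect_channels] = coupled.astype(np.float32)
        advance = (2 * np.pi * f_alpha * times).astype(np.float32)
        phases = offsets[:, :, None] + advance[None, None, :]

        power = rng.standard_normal((nk, n_chan, n_times), dtype=np.float32)
        power *= np.float32(power_map_noise)
        power[:, effect_channels, :] += pow_lat[keep, None, None].astype(np.float32)

        behavior = {
            "illusion_rate": behav["pooled"]["illusion_rate"],
            "criterion": behav["pooled"]["criterion"],
        }
        for d in design.directions:
            behavior[f"illusion_rate_{d}"] = behav[d]["illusion_rate"]
            behavior[f"criterion_{d}"] = behav[d]["criterion"]

        subjects.append(
            SubjectLatent(
                subject_id=profile.subject_id,
                labels=labels[keep_rel],
                directions=dirs[keep_rel],
                phases=phases,
                power=power,
                behavior=behavior,
            )
        )
    return Cohort(subjects=subjects, layout=layout, times=times, effect_sensors=effect_sensors)
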