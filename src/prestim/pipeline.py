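"""End-to-end orchestration: behavior -> spectral -> POS + correlation clustering.

Two entry points share one group-level inference core:

* :func:`run_pipeline` consumes raw per-subject epochs + trial tables and
  runs the full chain (classify, RT filter, equalize, Morlet, band average,
  planar combination, prestimulus restriction, then group statistics).
* :func:`run_cohort_analysis` consumes a band-level latent cohort from
  :func:`prestim.synth.simulate_latent_cohort` and runs the identical group
  statistics; this is the path used for large statistical validations.

The group statistics are: the pooled-direction POS cluster test against the
two-level permutation null; the pooled-direction ILL vs no-ILL power
contrast (subject-level sign-flip permutation test); per-direction
between-subject correlation cluster tests against illusion rate and
criterion; and the conjunction of the illusion-rate correlation maps across
directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import __version__
from .behavior import classify_trials, filter_rts, summarize_behavior
from .cluster import (
    ClusterConfig,
    SpatioTemporalGraph,
    cluster_permutation_correlation,
    cluster_permutation_pos,
    clusters_from_map,
    conjunction_test,
    _attach_p,
    _max_cluster_stat,
    ClusterTestResult,
)
from .phase_opposition import group_null, pos_from_phases, subject_null, zscore_pos
from .spectral import (
    MorletSpec,
    band_average,
    combine_planar,
    equalize_trials,
    extract_prestim,
    morlet_transform,
    reject_epochs,
)

__all__ = ["AnalysisConfig", "run_pipeline", "run_cohort_analysis", "power_contrast"]


@dataclass
class AnalysisConfig:
    """Parameters of the full analysis chain (defaults follow the study)."""

    prestim_window: tuple = (-0.6, -0.2)
    band: str = "alpha"
    bandwidth: float = 3.0
    rt_bounds: tuple = (0.2, 4.0)
    amplitude_threshold: float | None = None
    n_subject_perm: int = 1000
    n_group_perm: int = 10000
    n_boot: int = 2000
    corr_cluster: ClusterConfig = field(
        default_factory=lambda: ClusterConfig(forming_alpha=0.01, min_neighbors=2, n_permutations=4000)
    )
    pos_cluster: ClusterConfig = field(
        default_factory=lambda: ClusterConfig(min_neighbors=0, min_cluster_size=10)
    )
    contrast_cluster: ClusterConfig = field(
        default_factory=lambda: ClusterConfig(forming_alpha=0.01, min_neighbors=0, n_permutations=4000)
    )
    conjunction_cluster: ClusterConfig = field(
        default_factory=lambda: ClusterConfig(
            forming_alpha=0.01, min_neighbors=0, n_permutations=4000, cluster_stat="max"
        )
    )

    def validate(self):
        if not self.prestim_window[0] < self.prestim_window[1]:
            raise ValueError("prestim_window must be ordered")
        for n in (self.n_subject_perm, self.n_group_perm, self.n_boot):
            if n <= 0:
                raise ValueError("permutation/bootstrap counts must be positive")


def _seed_stream(seed):
    ss = np.random.SeedSequence(seed)
    while True:
        (child,) = ss.spawn(1)
        yield int(child.generate_state(1)[0] % (2**31))


def power_contrast(
    ill_power: np.ndarray,
    noill_power: np.ndarray,
    adjacency: np.ndarray,
    config: ClusterConfig | None = None,
    seed: int | None = None,
    graph: SpatioTemporalGraph | None = None,
) -> ClusterTestResult:
    """Paired ILL vs no-ILL power contrast with subject-level sign flipping.

    Inputs are per-subject mean prestimulus band-power maps with equalized
    trial counts.  The cluster-forming statistic is the one-sample t over
    subjects of the paired difference; the null flips the sign of each
    subject's difference map.
    """
    if config is None:
        config = ClusterConfig(forming_alpha=0.01, min_neighbors=0, n_permutations=4000)
    config.validate()
    ill_power = np.asarray(ill_power, float)
    noill_power = np.asarray(noill_power, float)
    if ill_power.shape != noill_power.shape:
        raise ValueError("unbalanced inputs: power maps must share shape")
    diff = ill_power - noill_power
    n = diff.shape[0]
    shape = diff.shape[1:]
    if graph is None:
        graph = SpatioTemporalGraph(adjacency, shape[1])
    rng = np.random.default_rng(seed)
    from scipy.stats import t as t_dist

    def t_map(d):
        sd = d.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = d.mean(axis=0) / (sd / np.sqrt(n))
        return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)

    t_crit = t_dist.ppf(1.0 - config.forming_alpha / 2.0, df=n - 1)
    obs_t = t_map(diff)
    obs_clusters = clusters_from_map(
        obs_t, -t_crit, t_crit, graph,
        min_neighbors=config.min_neighbors,
        min_cluster_size=config.min_cluster_size,
        stat_kind=config.cluster_stat,
    )
    null_max = np.empty(config.n_permutations)
    for k in range(config.n_permutations):
        flips = rng.choice([-1.0, 1.0], size=n)
        cl = clusters_from_map(
            t_map(diff * flips[:, None, None]), -t_crit, t_crit, graph,
            min_neighbors=config.min_neighbors,
            min_cluster_size=config.min_cluster_size,
            stat_kind=config.cluster_stat,
        )
        null_max[k] = _max_cluster_stat(cl)
    _attach_p(obs_clusters, null_max)
    return ClusterTestResult(
        clusters=obs_clusters,
        null_max=null_max,
        shape=shape,
        alpha_level=config.alpha_level,
        extra={"t": obs_t, "t_crit": t_crit},
    )


def _group_inference(
    *,
    pos_observed,          # list of (channels, T) subject POS maps
    pos_nulls,             # list of subject NullDistribution
    power_maps,            # dict: direction|'pooled' -> {'ILL': (n,S,T), 'no-ILL': ...}
    behavior,              # dict: measure_direction -> (n,) vector
    directions,
    adjacency,
    site_of_channel,
    planar: bool,
    config: AnalysisConfig,
    seeds,
):
    report = {}
    n_times = pos_observed[0].shape[-1]

    # --- POS arm (pooled directions) ---
    group_pos = np.mean(np.stack(pos_observed), axis=0)
    gnull = group_null(pos_nulls, n_draws=config.n_group_perm, seed=next(seeds))
    if planar:
        group_pos = combine_planar(group_pos, site_of_channel, axis=0)
        gsamples = combine_planar(gnull.samples, site_of_channel, axis=1)
    else:
        gsamples = gnull.samples
    z_map = zscore_pos(group_pos, gsamples)
    graph = SpatioTemporalGraph(adjacency, n_times)
    pos_result = cluster_permutation_pos(
        group_pos, gsamples, adjacency, config=config.pos_cluster, graph=graph
    )
    report["pos"] = pos_result.to_dict()
    report["pos"]["z_max"] = float(np.max(z_map))

    # --- pooled power contrast ---
    contrast = power_contrast(
        power_maps["pooled"]["ILL"],
        power_maps["pooled"]["no-ILL"],
        adjacency,
        config=config.contrast_cluster,
        seed=next(seeds),
        graph=graph,
    )
    report["power_contrast"] = contrast.to_dict()

    # --- per-direction correlations ---
    report["correlations"] = {}
    for d in directions:
        diff = power_maps[d]["ILL"] - power_maps[d]["no-ILL"]
        for measure in ("illusion_rate", "criterion"):
            res = cluster_permutation_correlation(
                diff,
                behavior[f"{measure}_{d}"],
                adjacency,
                config=config.corr_cluster,
                seed=next(seeds),
                graph=graph,
                measure=measure,
            )
            report["correlations"][f"{measure}_{d}"] = res.to_dict()

    # --- conjunction across directions (illusion rate) ---
    if len(directions) == 2:
        d1, d2 = directions
        conj = conjunction_test(
            power_maps[d1]["ILL"] - power_maps[d1]["no-ILL"],
            behavior[f"illusion_rate_{d1}"],
            power_maps[d2]["ILL"] - power_maps[d2]["no-ILL"],
            behavior[f"illusion_rate_{d2}"],
            adjacency,
            config=config.conjunction_cluster,
            seed=next(seeds),
            graph=graph,
        )
        report["conjunction"] = conj.to_dict()
    return report, {"pos_result": pos_result, "z_map": z_map, "contrast": contrast}


def run_cohort_analysis(cohort, config: AnalysisConfig | None = None, seed: int = 0):
    """Group statistics on a band-level latent cohort.

    Returns ``(report, results)`` where ``report`` is a JSON-ready dict and
    ``results`` holds the in-memory result objects.
    """
    if config is None:
        config = AnalysisConfig()
    config.validate()
    seeds = _seed_stream(seed)
    layout = cohort.layout
    directions = ("inward", "outward")

    pos_observed, pos_nulls = [], []
    for s in cohort.subjects:
        ill = s.labels == "ILL"
        obs, null = subject_null(
            s.phases, ill, n_perm=config.n_subject_perm, seed=next(seeds), return_observed=True
        )
        pos_observed.append(obs)
        pos_nulls.append(null)

    planar = layout.channel_kind == "planar_pair"
    power_maps = {}
    for key, d in (("pooled", None), ("inward", "inward"), ("outward", "outward")):
        maps = {"ILL": [], "no-ILL": []}
        for s in cohort.subjects:
            keep = np.ones(len(s.labels), bool) if d is None else s.directions == d
            power = s.power
            if planar:
                power = combine_planar(power, layout.site_of_channel, axis=1)
            for lab in ("ILL", "no-ILL"):
                maps[lab].append(power[keep & (s.labels == lab)].mean(axis=0))
        power_maps[key] = {lab: np.stack(v).astype(float) for lab, v in maps.items()}

    behavior = {}
    for measure in ("illusion_rate", "criterion"):
        for d in directions:
            behavior[f"{measure}_{d}"] = cohort.behavior_vector(measure, d)

    report, results = _group_inference(
        pos_observed=pos_observed,
        pos_nulls=pos_nulls,
        power_maps=power_maps,
        behavior=behavior,
        directions=directions,
        adjacency=layout.adjacency,
        site_of_channel=layout.site_of_channel,
        planar=planar,
        config=config,
        seeds=seeds,
    )
    report["behavior"] = {
        s.subject_id: {k: float(v) for k, v in s.behavior.items()} for s in cohort.subjects
    }
    report["provenance"] = _provenance(config, seed, len(cohort.subjects))
    return report, results


def run_pipeline(subject_data, layout, config: AnalysisConfig | None = None, seed: int = 0):
    """Full chain on raw data: list of ``(trials_df, EpochSet)`` per subject.

    Behavioral processing (classification, RT filter), epoch QC and trial
    equalization, Morlet band decomposition over the prestimulus window,
    planar combination where applicable, then the shared group statistics.
    Deterministic given the seed.
    """
    if config is None:
        config = AnalysisConfig()
    config.validate()
    if len(subject_data) < 4:
        raise ValueError("need at least 4 subjects")
    seeds = _seed_stream(seed)
    directions = ("inward", "outward")
    spec = MorletSpec.for_band(config.band, bandwidth=config.bandwidth)
    site_of = layout.site_of_channel
    planar = layout.channel_kind == "planar_pair"

    pos_observed, pos_nulls = [], []
    power_maps = {k: {"ILL": [], "no-ILL": []} for k in ("pooled", "inward", "outward")}
    behavior = {f"{m}_{d}": [] for m in ("illusion_rate", "criterion") for d in directions}
    behavior_report = {}

    for trials, epochs in subject_data:
        stage = "behavior"
        try:
            trials = classify_trials(trials)
            trials, _ = filter_rts(trials, *config.rt_bounds)
            summary = summarize_behavior(trials)
            behavior_report[epochs.subject_id] = _jsonable(summary)
            for d in directions:
                behavior[f"illusion_rate_{d}"].append(summary[d]["illusion_rate"])
                behavior[f"criterion_{d}"].append(summary[d]["criterion"])

            stage = "epoch selection"
            test = trials[trials["label"].isin(["ILL", "no-ILL"])]
            idx = np.flatnonzero(np.isin(epochs.trial_ids, test["trial"].to_numpy()))
            sel = epochs.select_trials(idx)
            order = test.set_index("trial")
            labels = order.loc[sel.trial_ids, "label"].to_numpy()
            dirs = order.loc[sel.trial_ids, "direction"].to_numpy()
            if config.amplitude_threshold is not None:
                sel, kept = reject_epochs(sel, config.amplitude_threshold)
                labels, dirs = labels[kept], dirs[kept]
            keep = equalize_trials(labels, dirs, seed=next(seeds))
            sel, labels, dirs = sel.select_trials(keep), labels[keep], dirs[keep]

            stage = "spectral"
            tf = extract_prestim(morlet_transform(sel, spec), config.prestim_window)
            phase = tf.phase                     # (trials, chan, F, T)
            power = band_average(tf.power, tf.freqs, config.band, freq_axis=2)
            if planar:
                power = combine_planar(power, site_of, axis=1)

            stage = "phase opposition"
            ill = labels == "ILL"
            obs, null = subject_null(
                phase, ill, n_perm=config.n_subject_perm, seed=next(seeds),
                freq_axis=1, return_observed=True,
            )
            pos_observed.append(obs)
            pos_nulls.append(null)

            stage = "power maps"
            for key, d in (("pooled", None), ("inward", "inward"), ("outward", "outward")):
                m = np.ones(len(labels), bool) if d is None else dirs == d
                for lab in ("ILL", "no-ILL"):
                    power_maps[key][lab].append(power[m & (labels == lab)].mean(axis=0))
        except Exception as err:
            raise RuntimeError(f"subject {epochs.subject_id}: stage '{stage}' failed: {err}") from err

    power_maps = {k: {lab: np.stack(v) for lab, v in d.items()} for k, d in power_maps.items()}
    behavior = {k: np.asarray(v, float) for k, v in behavior.items()}

    report, results = _group_inference(
        pos_observed=pos_observed,
        pos_nulls=pos_nulls,
        power_maps=power_maps,
        behavior=behavior,
        directions=directions,
        adjacency=layout.adjacency,
        site_of_channel=site_of,
        planar=planar,
        config=config,
        seeds=seeds,
    )
    report["behavior"] = behavior_report
    report["provenance"] = _provenance(config, seed, len(subject_data))
    return report, results


def _provenance(config, seed, n_subjects):
    return {
        "package": "prestim",
        "version": __version__,
        "seed": int(seed),
        "n_subjects": int(n_subjects),
        "config": _jsonable(asdict(config)),
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(_jsonable(report), f, indent=2)


def report_to_markdown(report: dict) -> str:
    """Human-readable digest of a run report."""
    def sig(res):
        return [c for c in res.get("clusters", []) if c["p_value"] < res.get("alpha_level", 0.05)]

    lines = ["# Prestimulus analysis report", ""]
    pos = report.get("pos", {})
    lines.append("## Phase opposition (POS), pooled directions")
    lines.append(
        f"- clusters: {len(pos.get('clusters', []))} ({len(sig(pos))} significant); "
        f"max z = {pos.get('z_max', float('nan')):.2f}"
    )
    for c in sig(pos):
        lines.append(f"  - T_sum = {c['stat']:.2f}, {c['n_points']} points, p = {c['p_value']:.4f}")
    pc = report.get("power_contrast", {})
    lines.append("## ILL vs no-ILL power contrast (pooled)")
    lines.append(f"- clusters: {len(pc.get('clusters', []))} ({len(sig(pc))} significant)")
    for c in sig(pc):
        lines.append(f"  - T_sum = {c['stat']:.2f}, p = {c['p_value']:.4f}")
    lines.append("## Between-subject correlations")
    for key, res in report.get("correlations", {}).items():
        lines.append(f"- {key}: {len(res['clusters'])} clusters, {len(sig(res))} significant")
        for c in sig(res):
            lines.append(f"  - T_sum = {c['stat']:.2f}, p = {c['p_value']:.4f}")
    conj = report.get("conjunction")
    if conj is not None:
        lines.append(f"## Conjunction across directions: {len(sig(conj))} significant clusters")
    return "\n".join(lines) + "\n"
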