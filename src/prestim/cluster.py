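"""Spatiotemporal cluster-permutation inference and supporting statistics.

Supra-threshold sensor-time points are clustered under combined spatial
(sensor-layout) and temporal (consecutive-sample) adjacency; positive and
negative points are clustered separately.  Family-wise correction compares
each observed cluster statistic against the permutation distribution of the
maximum cluster statistic.  Cluster p-values use the add-one rule
(count >= observed + 1) / (n_perm + 1) so they are never exactly zero.

Three engines are provided:

* :func:`cluster_permutation_pos` — POS maps against a group-level
  permutation null, pointwise percentile thresholds (2.5/97.5 by default),
  minimal cluster size 10, cluster statistic = sum.
* :func:`cluster_permutation_correlation` — between-subject Spearman
  correlation maps (t-transform cluster forming at alpha 0.01 two-sided,
  minimum 2 supra-threshold spatial neighbors), null by shuffling the
  behavioral vector across subjects.
* :func:`conjunction_test` — pointwise signed min-|r| across two correlation
  maps, null by re-shuffling subjects, cluster statistic = maximum over the
  cluster.

Circular helpers (Rayleigh test, circular mean) and the percentile bootstrap
CI for Spearman correlations live here as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata
from scipy.stats import t as t_dist

__all__ = [
    "ClusterConfig",
    "Cluster",
    "ClusterTestResult",
    "CorrelationMap",
    "SpatioTemporalGraph",
    "spearman_map",
    "clusters_from_map",
    "cluster_permutation_pos",
    "cluster_permutation_correlation",
    "conjunction_test",
    "bootstrap_ci",
    "rayleigh_test",
    "circular_mean",
]


@dataclass
class ClusterConfig:
    """Knobs of the permutation cluster tests.

    ``forming_alpha`` is the two-sided pointwise threshold used to form
    clusters (0.01 for the correlation tests); the POS test forms clusters
    from pointwise null percentiles (``pos_percentiles``) instead.
    """

    forming_alpha: float = 0.01
    min_neighbors: int = 2
    min_cluster_size: int = 0
    n_permutations: int = 4000
    alpha_level: float = 0.05
    cluster_stat: str = "sum"            # 'sum' | 'max'
    pos_percentiles: tuple = (2.5, 97.5)

    def validate(self):
        if not 0 < self.forming_alpha < 1:
            raise ValueError("forming_alpha must be in (0, 1)")
        if not 0 < self.alpha_level <= 1:
            raise ValueError("alpha_level must be in (0, 1]")
        if self.cluster_stat not in ("sum", "max"):
            raise ValueError("cluster_stat must be 'sum' or 'max'")


@dataclass
class Cluster:
    points: np.ndarray          # flat indices into the (sensor, time) map
    stat: float
    sign: int
    p_value: float | None = None

    def members(self, n_times: int):
        """(sensor, time) index pairs of the member points."""
        return np.stack(np.divmod(self.points, n_times), axis=1)


@dataclass
class ClusterTestResult:
    clusters: list
    null_max: np.ndarray
    shape: tuple
    alpha_level: float = 0.05
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p_value is not None and c.p_value < self.alpha_level]

    def to_dict(self) -> dict:
        n_times = self.shape[1]
        return {
            "alpha_level": self.alpha_level,
            "n_permutations": int(len(self.null_max)),
            "clusters": [
                {
                    "stat": float(c.stat),
                    "sign": int(c.sign),
                    "p_value": float(c.p_value),
                    "n_points": int(len(c.points)),
                    "members": c.members(n_times).tolist(),
                }
                for c in self.clusters
            ],
        }


class SpatioTemporalGraph:
    """Precomputed edge lists over the flattened sensor x time lattice.

    Spatial edges replicate the sensor adjacency at every time sample;
    temporal edges connect consecutive samples of each sensor.
    """

    def __init__(self, adjacency: np.ndarray, n_times: int):
        adjacency = np.asarray(adjacency, dtype=bool)
        if adjacency.shape[0] != adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        self.n_sensors = adjacency.shape[0]
        self.n_times = n_times
        self.adjacency = adjacency
        self._adj_sparse = sparse.csr_matrix(adjacency.astype(np.int32))
        su, sv = np.nonzero(np.triu(adjacency))
        t = np.arange(n_times)
        eu = [(su[:, None] * n_times + t[None, :]).ravel()]
        ev = [(sv[:, None] * n_times + t[None, :]).ravel()]
        s = np.arange(self.n_sensors)
        eu.append((s[:, None] * n_times + t[None, :-1]).ravel())
        ev.append((s[:, None] * n_times + t[None, 1:]).ravel())
        self.eu = np.concatenate(eu).astype(np.int64)
        self.ev = np.concatenate(ev).astype(np.int64)
        self.n_nodes = self.n_sensors * n_times

    def components(self, mask_flat: np.ndarray):
        """Connected components of the masked subgraph.

        Returns (labels, n_components); unmasked nodes get label -1.
        """
        keep = mask_flat[self.eu] & mask_flat[self.ev]
        g = sparse.coo_matrix(
            (np.ones(int(keep.sum()), dtype=np.int8), (self.eu[keep], self.ev[keep])),
            shape=(self.n_nodes, self.n_nodes),
        )
        n, labels = connected_components(g, directed=False)
        labels = labels.copy()
        labels[~mask_flat] = -1
        return labels, n

    def neighbor_counts(self, mask: np.ndarray) -> np.ndarray:
        """Per point, number of supra-threshold spatial neighbors at the same time."""
        return self._adj_sparse @ mask.astype(np.int32)


def _extract_clusters(stat_map, mask, graph, min_cluster_size, sign, stat_kind):
    flat = mask.ravel()
    if not flat.any():
        return []
    labels, _ = graph.components(flat)
    idx = np.flatnonzero(flat)
    lab = labels[idx]
    uniq, inv = np.unique(lab, return_inverse=True)
    sizes = np.bincount(inv)
    vals = stat_map.ravel()[idx]
    clusters = []
    for k in range(len(uniq)):
        if sizes[k] < max(min_cluster_size, 1):
            continue
        pts = idx[inv == k]
        v = stat_map.ravel()[pts]
        stat = float(v.sum()) if stat_kind == "sum" else float(v[np.argmax(np.abs(v))])
        clusters.append(Cluster(points=pts, stat=stat, sign=sign))
    return clusters


def clusters_from_map(
    stat_map: np.ndarray,
    lower,
    upper,
    graph: SpatioTemporalGraph,
    min_neighbors: int = 0,
    min_cluster_size: int = 0,
    stat_kind: str = "sum",
) -> list:
    """Supra-threshold clusters of a sensor x time map, split by sign.

    ``lower``/``upper`` may be scalars or per-point threshold maps.  Points
    above ``upper`` and points below ``lower`` are clustered separately.
    With ``min_neighbors`` > 0, points with fewer supra-threshold spatial
    neighbors (same sign, same time sample) are removed before clustering.
    Components smaller than ``min_cluster_size`` points are dropped.
    """
    stat_map = np.asarray(stat_map, float)
    out = []
    for sign, mask in ((1, stat_map > upper), (-1, stat_map < lower)):
        if min_neighbors > 0 and mask.any():
            mask = mask & (graph.neighbor_counts(mask) >= min_neighbors)
        out += _extract_clusters(stat_map, mask, graph, min_cluster_size, sign, stat_kind)
    return out


def _max_cluster_stat(clusters) -> float:
    return max((abs(c.stat) for c in clusters), default=0.0)


def _attach_p(clusters, null_max):
    n = len(null_max)
    for c in clusters:
        c.p_value = (np.sum(null_max >= abs(c.stat)) + 1.0) / (n + 1.0)
    return clusters


# ---------------------------------------------------------------------------
# POS cluster test


def cluster_permutation_pos(
    observed: np.ndarray,
    null_samples: np.ndarray,
    adjacency: np.ndarray,
    config: ClusterConfig | None = None,
    graph: SpatioTemporalGraph | None = None,
) -> ClusterTestResult:
    """Cluster test of a group POS map against the group-level permutation null.

    Pointwise thresholds are per sensor-time percentiles of the null
    (2.5/97.5 by default, a two-sided test at alpha = 0.05); components with
    fewer than ``min_cluster_size`` points (10 by default) are dropped.  The
    cluster statistic is the sum of POS inside the cluster; correction runs
    the identical clustering on every null draw and keeps the maximum
    absolute cluster statistic.
    """
    if config is None:
        config = ClusterConfig(min_cluster_size=10, min_neighbors=0)
    config.validate()
    observed = np.asarray(observed, float)
    null_samples = np.asarray(null_samples)
    n_draws = null_samples.shape[0]
    lo_q, hi_q = config.pos_percentiles
    if n_draws < max(100.0 / lo_q, 100.0 / (100.0 - hi_q)):
        raise ValueError("too few null draws for the requested percentiles")
    lo = np.percentile(null_samples, lo_q, axis=0)
    hi = np.percentile(null_samples, hi_q, axis=0)
    if graph is None:
        graph = SpatioTemporalGraph(adjacency, observed.shape[1])

    obs_clusters = clusters_from_map(
        observed, lo, hi, graph,
        min_neighbors=config.min_neighbors,
        min_cluster_size=config.min_cluster_size,
        stat_kind=config.cluster_stat,
    )
    null_max = np.empty(n_draws)
    hi_b = hi[None]
    lo_b = lo[None]
    for i in range(n_draws):
        draw = null_samples[i]
        cl = clusters_from_map(
            draw, lo_b[0], hi_b[0], graph,
            min_neighbors=config.min_neighbors,
            min_cluster_size=config.min_cluster_size,
            stat_kind=config.cluster_stat,
        )
        null_max[i] = _max_cluster_stat(cl)
    _attach_p(obs_clusters, null_max)
    return ClusterTestResult(
        clusters=obs_clusters,
        null_max=null_max,
        shape=observed.shape,
        alpha_level=config.alpha_level,
        extra={"thresholds": (lo, hi)},
    )


# ---------------------------------------------------------------------------
# between-subject correlation maps


@dataclass
class CorrelationMap:
    r: np.ndarray
    t: np.ndarray
    n_subjects: int
    behavioral_measure: str = ""


def _rank_center(x, axis=0):
    r = rankdata(x, axis=axis)
    r = r - r.mean(axis=axis, keepdims=True)
    return r


def _spearman_from_ranks(rb_c, rp_c):
    """Pointwise Spearman r between one centered rank vector and rank maps.

    rb_c: (n,) centered behavior ranks; rp_c: (n, P) centered power ranks.
    """
    num = rb_c @ rp_c
    den = np.sqrt((rb_c**2).sum()) * np.sqrt((rp_c**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.nan_to_num(r, nan=0.0)


def _t_transform(r, n):
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    # |r| = 1 -> infinite t; keep sign, cap to a large finite value
    t = np.where(np.isfinite(t), t, np.sign(r) * 1e12)
    return t


def spearman_map(power_diff: np.ndarray, behavior: np.ndarray, measure: str = "") -> CorrelationMap:
    """Pointwise Spearman correlation (average-rank ties) across subjects.

    ``power_diff`` is (n_subjects, sensors, times); ``behavior`` a
    per-subject scalar.  The t-transform t = r sqrt((n-2)/(1-r^2)) is
    attached for cluster forming.
    """
    power_diff = np.asarray(power_diff, float)
    behavior = np.asarray(behavior, float)
    n = len(behavior)
    if power_diff.shape[0] != n:
        raise ValueError("subject axes must align")
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(behavior) == 0:
        raise ValueError("behavioral vector is constant")
    shape = power_diff.shape[1:]
    rp_c = _rank_center(power_diff.reshape(n, -1))
    rb_c = _rank_center(behavior)
    r = _spearman_from_ranks(rb_c, rp_c).reshape(shape)
    return CorrelationMap(r=r, t=_t_transform(r, n), n_subjects=n, behavioral_measure=measure)


def cluster_permutation_correlation(
    power_diff: np.ndarray,
    behavior: np.ndarray,
    adjacency: np.ndarray,
    config: ClusterConfig | None = None,
    seed: int | None = None,
    graph: SpatioTemporalGraph | None = None,
    measure: str = "",
) -> ClusterTestResult:
    """Cluster-corrected between-subject Spearman correlation map.

    Clusters form where |t(r)| exceeds the two-sided ``forming_alpha``
    Student-t quantile (df = n - 2) and survive the ``min_neighbors`` spatial
    filter; the cluster statistic is the sum of t.  The null shuffles the
    subjects of the behavioral vector (4000 permutations by default);
    positive and negative clusters share one max-|sum| null.
    """
    if config is None:
        config = ClusterConfig()
    config.validate()
    if config.n_permutations < 100:
        import warnings

        warnings.warn("fewer than 100 permutations; p-values will be coarse")
    power_diff = np.asarray(power_diff, float)
    behavior = np.asarray(behavior, float)
    n = len(behavior)
    shape = power_diff.shape[1:]
    if graph is None:
        graph = SpatioTemporalGraph(adjacency, shape[1])
    rng = np.random.default_rng(seed)

    rp_c = _rank_center(power_diff.reshape(n, -1))
    rb_c = _rank_center(behavior)
    t_crit = t_dist.ppf(1.0 - config.forming_alpha / 2.0, df=n - 2)

    def t_map(rb):
        return _t_transform(_spearman_from_ranks(rb, rp_c).reshape(shape), n)

    obs_t = t_map(rb_c)
    obs_clusters = clusters_from_map(
        obs_t, -t_crit, t_crit, graph,
        min_neighbors=config.min_neighbors,
        min_cluster_size=config.min_cluster_size,
        stat_kind=config.cluster_stat,
    )
    null_max = np.empty(config.n_permutations)
    for k in range(config.n_permutations):
        perm_t = t_map(rb_c[rng.permutation(n)])
        cl = clusters_from_map(
            perm_t, -t_crit, t_crit, graph,
            min_neighbors=config.min_neighbors,
            min_cluster_size=config.min_cluster_size,
            stat_kind=config.cluster_stat,
        )
        null_max[k] = _max_cluster_stat(cl)
    _attach_p(obs_clusters, null_max)
    obs_r = _spearman_from_ranks(rb_c, rp_c).reshape(shape)
    return ClusterTestResult(
        clusters=obs_clusters,
        null_max=null_max,
        shape=shape,
        alpha_level=config.alpha_level,
        extra={"r": obs_r, "t": obs_t, "t_crit": t_crit, "measure": measure},
    )


# ---------------------------------------------------------------------------
# conjunction across directions


def _signed_min_abs(r_a, r_b):
    """Pointwise conjunction: signed min |r|; 0 where the signs disagree."""
    agree = np.sign(r_a) == np.sign(r_b)
    mag = np.minimum(np.abs(r_a), np.abs(r_b))
    return np.where(agree, np.sign(r_a) * mag, 0.0)


def conjunction_test(
    power_diff_a: np.ndarray,
    behavior_a: np.ndarray,
    power_diff_b: np.ndarray,
    behavior_b: np.ndarray,
    adjacency: np.ndarray,
    config: ClusterConfig | None = None,
    seed: int | None = None,
    graph: SpatioTemporalGraph | None = None,
) -> ClusterTestResult:
    """Conjunction of two correlation maps (e.g. inward/outward directions).

    The conjunction value keeps, per point, the lowest absolute correlation
    coefficient between the two maps (signed; zero when the signs disagree).
    The null re-shuffles the subjects of each behavioral vector
    independently; pointwise thresholds are the two-sided ``forming_alpha``
    percentiles of the null conjunction values, and the cluster statistic is
    the maximum over the cluster.
    """
    if config is None:
        config = ClusterConfig(min_neighbors=0, cluster_stat="max")
    config.validate()
    a = np.asarray(power_diff_a, float)
    b = np.asarray(power_diff_b, float)
    if a.shape != b.shape:
        raise ValueError("both maps must share geometry")
    n = a.shape[0]
    shape = a.shape[1:]
    if graph is None:
        graph = SpatioTemporalGraph(adjacency, shape[1])
    rng = np.random.default_rng(seed)

    rpa = _rank_center(a.reshape(n, -1))
    rpb = _rank_center(b.reshape(n, -1))
    rba = _rank_center(np.asarray(behavior_a, float))
    rbb = _rank_center(np.asarray(behavior_b, float))

    def conj(rb1, rb2):
        ra = _spearman_from_ranks(rb1, rpa)
        rb = _spearman_from_ranks(rb2, rpb)
        return _signed_min_abs(ra, rb).reshape(shape)

    observed = conj(rba, rbb)
    n_perm = config.n_permutations
    null = np.empty((n_perm,) + shape, dtype=np.float32)
    for k in range(n_perm):
        null[k] = conj(rba[rng.permutation(n)], rbb[rng.permutation(n)])
    lo = np.percentile(null, 100.0 * config.forming_alpha / 2.0, axis=0)
    hi = np.percentile(null, 100.0 * (1.0 - config.forming_alpha / 2.0), axis=0)

    obs_clusters = clusters_from_map(
        observed, lo, hi, graph,
        min_neighbors=config.min_neighbors,
        min_cluster_size=config.min_cluster_size,
        stat_kind="max",
    )
    null_max = np.empty(n_perm)
    for k in range(n_perm):
        cl = clusters_from_map(
            null[k], lo, hi, graph,
            min_neighbors=config.min_neighbors,
            min_cluster_size=config.min_cluster_size,
            stat_kind="max",
        )
        null_max[k] = _max_cluster_stat(cl)
    _attach_p(obs_clusters, null_max)
    return ClusterTestResult(
        clusters=obs_clusters,
        null_max=null_max,
        shape=shape,
        alpha_level=config.alpha_level,
        extra={"observed": observed, "thresholds": (lo, hi)},
    )


# ---------------------------------------------------------------------------
# bootstrap and circular statistics


def _spearman_r(x, y):
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    den = np.sqrt((rx**2).sum() * (ry**2).sum())
    if den == 0:
        return np.nan
    return float((rx * ry).sum() / den)


def bootstrap_ci(
    x: np.ndarray,
    y: np.ndarray,
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
):
    """Percentile bootstrap CI for the Spearman correlation of paired vectors.

    Subjects are resampled with replacement; resamples where either vector is
    constant are skipped (and counted).  Returns
    ``(low, high, r_observed, n_skipped)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired vectors must have equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 subjects")
    rng = np.random.default_rng(seed)
    r_obs = _spearman_r(x, y)
    draws = np.empty(n_boot)
    skipped = 0
    k = 0
    attempts = 0
    while k < n_boot and attempts < 20 * n_boot:
        attempts += 1
        idx = rng.integers(len(x), size=len(x))
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            skipped += 1
            continue
        draws[k] = _spearman_r(x[idx], y[idx])
        k += 1
    draws = draws[:k]
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(draws, [tail, 100.0 - tail])
    return float(lo), float(hi), r_obs, skipped


def rayleigh_test(angles) -> tuple:
    """Rayleigh test of circular uniformity.

    Returns ``(Z, p)`` with Z = n * Rbar**2 and the standard small-sample
    correction p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)) where R is the
    resultant length.
    """
    angles = np.asarray(angles, float)
    angles = angles[np.isfinite(angles)]
    n = len(angles)
    if n < 2:
        raise ValueError("need at least 2 finite angles")
    resultant = np.abs(np.sum(np.exp(1j * angles)))
    z = resultant**2 / n
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - resultant**2)) - (1.0 + 2.0 * n))
    return float(z), float(min(p, 1.0))


def circular_mean(angles) -> float:
    """Mean direction (radians, in (-pi, pi]) of the unit phasors."""
    angles = np.asarray(angles, float)
    if len(angles) == 0:
        raise ValueError("need at least 1 angle")
    mean_phasor = np.mean(np.exp(1j * angles))
    if np.abs(mean_phasor) < 1e-12:
        raise ValueError("zero resultant: circular mean undefined")
    ang = float(np.angle(mean_phasor))
    return np.pi if np.isclose(ang, -np.pi) else ang
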