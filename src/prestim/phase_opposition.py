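"""Phase opposition sum (POS) and its two-level permutation null.

POS = ITC_ILL + ITC_no-ILL - 2 * ITC_all.  With equal trial counts per
condition, POS is near zero when both conditions share the same phase
distribution and approaches 2 when the two conditions are perfectly locked at
opposite phases (the pooled phasors cancel).

Inference follows a two-level resampling scheme: a subject-level null built
by shuffling the ILL/no-ILL labels and recomputing POS over all sensors and
time points (n = 1000 by default), then a group-level null built by drawing
one subject-level sample per individual and averaging (n = 10,000 by
default).  The observed group POS is z-scored against the group null; cluster
inference is delegated to :mod:`prestim.cluster`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NullDistribution",
    "compute_pos",
    "pos_from_phases",
    "subject_null",
    "group_null",
    "zscore_pos",
]


@dataclass
class NullDistribution:
    """Permutation samples of POS maps at subject or group level."""

    level: str                 # 'subject' | 'group'
    samples: np.ndarray        # (n_permutations, ...) float32
    seed: int | None = None

    @property
    def n_permutations(self) -> int:
        return self.samples.shape[0]


def compute_pos(itc_ill, itc_noill, itc_all) -> np.ndarray:
    """Pointwise POS from the three ITC maps (aligned shapes required)."""
    itc_ill, itc_noill, itc_all = map(np.asarray, (itc_ill, itc_noill, itc_all))
    if not (itc_ill.shape == itc_noill.shape == itc_all.shape):
        raise ValueError("ITC maps must share one shape")
    return itc_ill + itc_noill - 2.0 * itc_all


def _pos_from_sums(sum_ill_re, sum_ill_im, tot_re, tot_im, n_ill, n_noill):
    # hot path of the permutation null: stays in float32 and reuses buffers
    inv_ill = np.float32(1.0 / n_ill)
    inv_noill = np.float32(1.0 / n_noill)
    inv_all = np.float32(1.0 / (n_ill + n_noill))
    itc_all = np.sqrt(tot_re * tot_re + tot_im * tot_im) * inv_all

    acc = sum_ill_re * sum_ill_re
    acc += sum_ill_im * sum_ill_im
    np.sqrt(acc, out=acc)
    acc *= inv_ill                      # acc = ITC_ill

    d_re = tot_re - sum_ill_re
    d_re *= d_re
    d_im = tot_im - sum_ill_im
    d_im *= d_im
    d_re += d_im
    np.sqrt(d_re, out=d_re)
    d_re *= inv_noill                   # d_re = ITC_noill

    acc += d_re
    acc -= np.float32(2.0) * itc_all
    return acc


def _phasor_parts(phases):
    ph = np.asarray(phases)
    flat = ph.reshape(ph.shape[0], -1)
    return np.cos(flat, dtype=np.float32), np.sin(flat, dtype=np.float32), ph.shape[1:]


def pos_from_phases(phases, ill_mask, freq_axis: int | None = None) -> np.ndarray:
    """Observed POS from single-trial phases (axis 0 = trials).

    When the phase array carries a frequency axis, the three ITCs are
    computed per center frequency and averaged across the band *before*
    forming the POS (``freq_axis`` counts axes of the per-trial map, i.e. of
    ``phases[1:]``).
    """
    ill_mask = np.asarray(ill_mask, bool)
    n_ill = int(ill_mask.sum())
    n_noill = int((~ill_mask).sum())
    if n_ill < 2 or n_noill < 2:
        raise ValueError("both conditions need at least 2 trials")
    re, im, shape = _phasor_parts(phases)
    tot_re, tot_im = re.sum(axis=0), im.sum(axis=0)
    s_re, s_im = re[ill_mask].sum(axis=0), im[ill_mask].sum(axis=0)
    pos = _pos_from_sums(s_re, s_im, tot_re, tot_im, n_ill, n_noill).reshape(shape)
    if freq_axis is not None:
        pos = pos.mean(axis=freq_axis)
    return pos.astype(np.float64)


def subject_null(
    phases,
    ill_mask,
    n_perm: int = 1000,
    seed: int | None = None,
    freq_axis: int | None = None,
    return_observed: bool = False,
):
    """Subject-level POS null: label shuffles preserving the ILL count.

    Implemented as a permutation-indicator matrix product with the per-trial
    phasors so the full sensors x time map is recomputed for every shuffle in
    one pass.  With ``return_observed`` the observed POS map (true labels) is
    computed from the same phasors and returned as ``(observed, null)``.
    """
    ill_mask = np.asarray(ill_mask, bool)
    n = len(ill_mask)
    n_ill = int(ill_mask.sum())
    n_noill = n - n_ill
    if n_ill == 0 or n_noill == 0:
        raise ValueError("both labels must be present")
    rng = np.random.default_rng(seed)
    re, im, shape = _phasor_parts(phases)
    tot_re, tot_im = re.sum(axis=0), im.sum(axis=0)

    ind = np.zeros((n_perm, n), dtype=np.float32)
    for k in range(n_perm):
        ind[k, rng.permutation(n)[:n_ill]] = 1.0
    s_re = ind @ re
    s_im = ind @ im
    pos = _pos_from_sums(s_re, s_im, tot_re[None], tot_im[None], n_ill, n_noill)
    pos = pos.reshape((n_perm,) + shape)
    if freq_axis is not None:
        pos = pos.mean(axis=freq_axis + 1)
    null = NullDistribution(level="subject", samples=pos.astype(np.float32, copy=False), seed=seed)
    if not return_observed:
        return null
    obs = _pos_from_sums(
        re[ill_mask].sum(axis=0), im[ill_mask].sum(axis=0), tot_re, tot_im, n_ill, n_noill
    ).reshape(shape)
    if freq_axis is not None:
        obs = obs.mean(axis=freq_axis)
    return obs.astype(np.float64), null


def group_null(
    subject_nulls: list,
    n_draws: int = 10000,
    seed: int | None = None,
    replace: bool = True,
) -> NullDistribution:
    """Group-level null: average one randomly chosen sample per subject.

    Draws are taken with replacement from each subject's permutation samples
    (the default allows n_draws to exceed the per-subject count).
    """
    if not subject_nulls:
        raise ValueError("need at least one subject null")
    mats = [nd.samples if isinstance(nd, NullDistribution) else np.asarray(nd) for nd in subject_nulls]
    shape = mats[0].shape[1:]
    if any(m.shape[1:] != shape for m in mats):
        raise ValueError("subject nulls must share map shape")
    rng = np.random.default_rng(seed)
    out = np.zeros((n_draws,) + shape, dtype=np.float32)
    for m in mats:
        m = m.astype(np.float32, copy=False)
        if replace:
            idx = rng.integers(m.shape[0], size=n_draws)
        else:
            if n_draws > m.shape[0]:
                raise ValueError("n_draws exceeds subject samples with replace=False")
            idx = rng.permutation(m.shape[0])[:n_draws]
        out += m[idx]
    out /= np.float32(len(mats))
    return NullDistribution(level="group", samples=out.astype(np.float32), seed=seed)


def zscore_pos(observed: np.ndarray, null: NullDistribution) -> np.ndarray:
    """Z-score the observed POS against the group-null mean and SD, pointwise."""
    samples = null.samples if isinstance(null, NullDistribution) else np.asarray(null)
    if samples.shape[0] < 2:
        raise ValueError("null needs at least 2 samples")
    mu = samples.mean(axis=0, dtype=np.float64)
    sd = samples.std(axis=0, ddof=1, dtype=np.float64)
    if np.any(sd == 0):
        raise ValueError("null SD is zero at some points")
    return (np.asarray(observed, np.float64) - mu) / sd
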