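"""Behavioral layer: trial classification, RT filtering, illusion rates, and
the signal-detection criterion.

The criterion uses an adapted confusion matrix: the hit rate H is the
proportion of control trials correctly perceived (their second flash really is
at the intermediate position), the false-alarm rate FA is the proportion of
test trials reported as illusory, and

    c = -(z(H) + z(FA)) / 2

with z the standard-normal quantile.  Negative c = liberal bias toward
reporting the illusion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .containers import CONDITIONS, RESPONSES

__all__ = [
    "filter_rts",
    "classify_trials",
    "compute_criterion",
    "summarize_behavior",
]


def filter_rts(trials: pd.DataFrame, low: float = 0.2, high: float = 4.0):
    """Drop trials with RT < ``low`` or RT > ``high`` seconds.

    Returns ``(filtered, rejected_fraction)``.  Idempotent: re-filtering the
    output removes nothing.
    """
    if low >= high:
        raise ValueError("low must be < high")
    if "rt" not in trials.columns or trials["rt"].isna().any():
        raise ValueError("all trials must have an RT")
    rt = trials["rt"].to_numpy(dtype=float)
    keep = (rt >= low) & (rt <= high)
    rejected = 1.0 - keep.mean() if len(trials) else 0.0
    return trials.loc[keep].reset_index(drop=True), rejected


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Assign perceptual labels from (condition, response).

    test + intermediate -> ILL; test + not-intermediate -> no-ILL;
    control trials are CTRL-correct when reported intermediate (their true
    position) and CTRL-incorrect otherwise.  Incorrect control trials are
    flagged ``excluded`` since only correct ones enter the control analyses.
    """
    out = trials.copy()
    if len(out) == 0:
        out["label"] = pd.Series(dtype=object)
        out["excluded"] = pd.Series(dtype=bool)
        return out
    bad_cond = ~out["condition"].isin(CONDITIONS)
    bad_resp = ~out["response"].isin(RESPONSES)
    if bad_cond.any() or bad_resp.any():
        raise ValueError("unknown condition or response codes")
    is_test = out["condition"] == "test"
    is_int = out["response"] == "intermediate"
    label = np.where(
        is_test,
        np.where(is_int, "ILL", "no-ILL"),
        np.where(is_int, "CTRL-correct", "CTRL-incorrect"),
    )
    out["label"] = label
    out["excluded"] = label == "CTRL-incorrect"
    return out


def _edge_correct(p: float, n: int | None, rule: str) -> float:
    if 0.0 < p < 1.0:
        return p
    if rule == "none" or n is None:
        raise ValueError(
            "H or FA is exactly 0 or 1; trial counts are required for edge correction"
        )
    if rule == "half_count":
        return 1.0 / (2 * n) if p <= 0.0 else 1.0 - 1.0 / (2 * n)
    raise ValueError(f"unknown edge correction rule {rule!r}")


def compute_criterion(
    H: float,
    FA: float,
    n_control: int | None = None,
    n_test: int | None = None,
    edge_correction: str = "half_count",
) -> float:
    """Signal-detection criterion c = -(z(H) + z(FA)) / 2.

    Degenerate rates (exactly 0 or 1) are replaced by 1/(2N) resp. 1 - 1/(2N)
    when the relevant trial count is given ('half_count' rule); otherwise an
    error is raised.  A log-linear correction (add 0.5 to all four cells) is a
    documented alternative but is not implemented here.
    """
    if not (0.0 <= H <= 1.0 and 0.0 <= FA <= 1.0):
        raise ValueError("H and FA must lie in [0, 1]")
    H = _edge_correct(float(H), n_control, edge_correction)
    FA = _edge_correct(float(FA), n_test, edge_correction)
    # complementary rates give c = 0 identically; short-circuit within one ulp
    # of H + FA = 1 so the identity holds exactly in floating point
    if abs((H + FA) - 1.0) < 4e-16:
        return 0.0
    return -(_z(H) + _z(FA)) / 2.0


def _z(p: float) -> float:
    # symmetrized normal quantile: exact antisymmetry z(p) = -z(1-p) in floating point
    return (ndtri(p) - ndtri(1.0 - p)) / 2.0


def _summary_for(sub: pd.DataFrame) -> dict:
    counts = sub["label"].value_counts().to_dict()
    n_ill = counts.get("ILL", 0)
    n_noill = counts.get("no-ILL", 0)
    n_cc = counts.get("CTRL-correct", 0)
    n_ci = counts.get("CTRL-incorrect", 0)
    n_test = n_ill + n_noill
    n_ctrl = n_cc + n_ci
    if n_test == 0:
        raise ValueError("no test trials in this direction")
    fa = n_ill / n_test
    h = n_cc / n_ctrl if n_ctrl else np.nan
    mean_rt = {
        lab: float(sub.loc[sub["label"] == lab, "rt"].mean()) if counts.get(lab, 0) else np.nan
        for lab in ("ILL", "no-ILL", "CTRL-correct", "CTRL-incorrect")
    }
    c = (
        compute_criterion(h, fa, n_control=n_ctrl, n_test=n_test)
        if n_ctrl
        else np.nan
    )
    return {
        "illusion_rate": fa,
        "control_accuracy": h,
        "H": h,
        "FA": fa,
        "criterion": c,
        "mean_rt": mean_rt,
        "n_trials": {"ILL": n_ill, "no-ILL": n_noill, "CTRL-correct": n_cc, "CTRL-incorrect": n_ci},
    }


def summarize_behavior(trials: pd.DataFrame) -> dict:
    """Per-direction and pooled rates, criterion, and RT means per label.

    Requires labeled trials (see :func:`classify_trials`).  Raises if any
    direction lacks test trials.
    """
    if "label" not in trials.columns:
        raise ValueError("trials must be labeled first (classify_trials)")
    out = {}
    for direction, sub in trials.groupby("direction"):
        out[direction] = _summary_for(sub)
    out["pooled"] = _summary_for(trials)
    return out
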