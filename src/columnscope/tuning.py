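"""Distance tuning of column responses in the event-related experiment.

Faces are flashed at nine virtual distances expressed as percentages of each
subject's personal-space (PS) boundary. Per-distance response amplitudes are
estimated with a GLM (one regressor per distance) and averaged within each
column type's ROI. Approach-biased columns are expected to respond only
inside the PS boundary, increasing steeply and monotonically toward the
nearest distance; withdrawal-biased columns show the sign-inverted profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .geometry import PS_GRID_PERCENTAGES
from .synthetic import BoldRun


def approach_profile(pct: np.ndarray | float, scale: float = 2.0) -> np.ndarray:
    """Generator amplitude profile of an approach-biased column.

    Zero at and beyond the PS boundary (100%), rising steeply and
    monotonically with proximity inside it: amp = scale * max(0, 100/pct - 1).
    """
    pct = np.asarray(pct, float)
    return scale * np.maximum(0.0, 100.0 / pct - 1.0)


def withdrawal_profile(pct: np.ndarray | float, scale: float = 1.0) -> np.ndarray:
    """Sign-inverted, shallower counterpart of the approach profile."""
    return -approach_profile(pct, scale=scale)


def event_response_amplitudes(
    run: BoldRun,
    roi_masks: dict[str, np.ndarray],
    drift_order: int = 2,
    use_motion: bool = True,
) -> pd.DataFrame:
    """ROI-mean response amplitude per distance condition.

    Fits a GLM with one regressor per event condition (the condition labels
    are the distance percentages) and averages the per-vertex betas within
    each ROI mask. Returns a long table: roi, condition, distance_pct, beta,
    beta_sd (across ROI vertices), n_events.

    Raises
    ------
    ValueError
        If a requested distance condition never occurs in the run.
    """
    design = glm.build_design_matrix(
        run.events, run.n_timepoints, run.tr,
        motion=run.motion if use_motion else None, drift_order=drift_order)
    fit = glm.fit_glm(run.flat_series(), design)
    n_events = run.events.groupby("condition").size()
    rows = []
    for roi_name, mask in roi_masks.items():
        flat = np.asarray(mask, bool).ravel()
        if not flat.any():
            raise ValueError(f"ROI {roi_name!r} is empty")
        for cond in design.condition_names:
            betas = fit.betas[design.column(f"cond:{cond}")][flat]
            rows.append({
                "roi": roi_name,
                "condition": cond,
                "distance_pct": float(cond),
                "beta": float(betas.mean()),
                "beta_sd": float(betas.std(ddof=1)) if betas.size > 1 else 0.0,
                "n_events": int(n_events[cond]),
            })
    return pd.DataFrame(rows)


@dataclass
class TuningCurve:
    """Response amplitude versus PS-normalized distance for one column type."""

    distances_pct: np.ndarray  # strictly increasing
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    column_type: str = ""
    ps_boundary_cm: float = np.nan

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.distances_pct) > 0):
            raise ValueError("distances must be strictly increasing")
        if not (len(self.distances_pct) == len(self.mean) == len(self.sd)
                == len(self.n)):
            raise ValueError("curve fields must have equal length")

    def inside(self) -> np.ndarray:
        return self.distances_pct <= 100.0

    def outside(self) -> np.ndarray:
        return self.distances_pct > 100.0


def build_tuning_curve(
    betas: pd.DataFrame,
    ps_boundary_cm: float = np.nan,
    column_type: str = "",
    expected_pcts: tuple[float, ...] = PS_GRID_PERCENTAGES,
) -> TuningCurve:
    """Order per-distance betas into a tuning curve (ascending distance).

    ``betas`` is the per-ROI slice of :func:`event_response_amplitudes`
    (columns distance_pct, beta, beta_sd, n_events), in any row order.
    """
    missing = set(expected_pcts) - set(betas["distance_pct"])
    if missing:
        raise ValueError(f"betas missing grid distances: {sorted(missing)}")
    b = betas.sort_values("distance_pct")
    return TuningCurve(
        distances_pct=b["distance_pct"].to_numpy(float),
        mean=b["beta"].to_numpy(float),
        sd=b["beta_sd"].to_numpy(float),
        n=b["n_events"].to_numpy(int),
        column_type=column_type,
        ps_boundary_cm=ps_boundary_cm,
    )


def _outside_null(curve: TuningCurve, alpha: float) -> bool:
    """Are all outside-PS amplitudes statistically indistinguishable from 0?"""
    out = curve.outside()
    for m, s, n in zip(curve.mean[out], curve.sd[out], curve.n[out]):
        if s == 0:
            if m != 0:
                return False
            continue
        t = m / (s / np.sqrt(n))
        p = 2 * stats.t.sf(abs(t), n - 1)
        if p < alpha:
            return False
    return True


def _monotone_decreasing(pct: np.ndarray, mean: np.ndarray,
                         alpha: float) -> bool:
    rho, p = stats.spearmanr(pct, mean)
    return bool(rho < 0 and p < alpha)


def classify_tuning(curve: TuningCurve, alpha: float = 0.05) -> str:
    """Classify a curve as 'approach_type', 'withdrawal_type', or 'flat'.

    approach_type: outside-PS amplitudes consistent with 0, inside-PS
    amplitudes positive and monotonically decreasing with distance
    (Spearman). withdrawal_type: the sign-inverted criteria. Anything else is
    'flat'. Classification is equivariant under negating the curve.
    """
    inside = curve.inside()
    pct_in = curve.distances_pct[inside]
    mean_in = curve.mean[inside]
    if _outside_null(curve, alpha):
        if np.all(mean_in[pct_in < 100.0] > 0) and _monotone_decreasing(
                pct_in, mean_in, alpha):
            return "approach_type"
        if np.all(mean_in[pct_in < 100.0] < 0) and _monotone_decreasing(
                pct_in, -mean_in, alpha):
            return "withdrawal_type"
    return "flat"


def estimate_boundary(
    curve: TuningCurve,
    candidates: tuple[float, ...] | None = None,
) -> float:
    """Estimate the PS boundary (in % units) from an approach-type curve.

    Fits, for each candidate boundary b on the grid, the one-parameter model
    amp(d) = c * max(0, b/d - 1) by least squares and returns the candidate
    with the smallest residual. Nearest-grid accuracy by construction.
    """
    if candidates is None:
        candidates = tuple(curve.distances_pct)
    best_b, best_sse = np.nan, np.inf
    y = curve.mean
    for b in candidates:
        basis = np.maximum(0.0, b / curve.distances_pct - 1.0)
        denom = float(basis @ basis)
        c = float(basis @ y) / denom if denom > 0 else 0.0
        sse = float(np.sum((y - c * basis) ** 2))
        if sse < best_sse:
            best_b, best_sse = float(b), sse
    return best_b
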