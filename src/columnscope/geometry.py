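"""Stimulus geometry of virtual-distance face stimuli and stop-distance stats.

Virtual distance is rendered on a fixed screen by co-varying face size and
binocular disparity. With a face of physical width ``w`` viewed at virtual
distance ``d`` and a screen at distance ``D``, similar triangles give the
on-screen width ``w * D / d``; the angular width is ``2 atan(w / 2d)`` and the
binocular disparity subtended by an interpupillary distance ``ipd`` is
``2 atan(ipd / 2d)``, realized as opposite per-eye mesh rotations of half that
angle each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SDPTrials

#: distances of the event-related experiment, as % of the personal-space
#: boundary: four inside, the boundary itself, and four outside.
PS_GRID_PERCENTAGES = (37.0, 57.0, 76.0, 91.0, 100.0, 182.0, 295.0, 419.0, 524.0)


@dataclass
class ViewingGeometry:
    """Physical viewing setup for the virtual-distance stimuli (cm, cm/s)."""

    screen_distance: float = 114.0
    face_width: float = 16.0
    ipd: float = 6.0
    speed: float = 112.0
    distance_range: tuple[float, float] = (39.0, 300.0)

    def __post_init__(self) -> None:
        vals = (self.screen_distance, self.face_width, self.ipd, self.speed,
                *self.distance_range)
        if any(v <= 0 for v in vals):
            raise ValueError("all geometry parameters must be positive")
        if self.distance_range[0] >= self.distance_range[1]:
            raise ValueError("distance_range must satisfy near < far")


def project_face(geom: ViewingGeometry, virtual_distance: float) -> dict[str, float]:
    """Screen size and disparity parameters of a face at a virtual distance.

    Returns ``screen_width_cm`` (similar triangles), ``angular_width_deg`` and
    ``disparity_angle_deg`` (exact 2-atan forms), and ``rotation_deg`` (the
    per-eye mesh rotation, half the disparity angle).
    """
    if virtual_distance <= 0:
        raise ValueError("virtual distance must be positive")
    screen_width = geom.face_width * geom.screen_distance / virtual_distance
    angular_width = np.degrees(2 * np.arctan(geom.face_width / 2 / virtual_distance))
    disparity = np.degrees(2 * np.arctan(geom.ipd / 2 / virtual_distance))
    return {
        "screen_width_cm": screen_width,
        "angular_width_deg": angular_width,
        "disparity_angle_deg": disparity,
        "rotation_deg": disparity / 2,
    }


def trajectory_frames(
    geom: ViewingGeometry,
    direction: str = "approach",
    frame_rate: float = 60.0,
) -> np.ndarray:
    """Virtual distances (cm) of a constant-speed traverse, frame by frame.

    The approach sequence runs from far to near across ``distance_range`` at
    ``geom.speed``; the withdrawal sequence is its exact reverse.
    """
    if frame_rate <= 0:
        raise ValueError("frame rate must be positive")
    if direction not in ("approach", "withdrawal"):
        raise ValueError("direction must be 'approach' or 'withdrawal'")
    near, far = geom.distance_range
    step = geom.speed / frame_rate
    distances = np.arange(far, near - 1e-9, -step)
    if direction == "withdrawal":
        distances = distances[::-1]
    return distances


@dataclass
class DistanceGrid:
    """The nine event-related virtual distances for one subject."""

    ps_boundary: float
    percentages: tuple[float, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.distances) > 0):
            raise ValueError("distances must be strictly increasing")


def ps_distance_grid(
    ps_boundary: float,
    percentages: tuple[float, ...] = PS_GRID_PERCENTAGES,
) -> DistanceGrid:
    """Virtual distances at fixed percentages of a subject's PS boundary."""
    if ps_boundary <= 0:
        raise ValueError("PS boundary must be positive")
    pct = np.asarray(percentages, float)
    return DistanceGrid(
        ps_boundary=ps_boundary,
        percentages=tuple(pct),
        distances=pct * ps_boundary / 100.0,
    )


@dataclass
class SDPSummary:
    """Per-subject stop-distance summaries plus the repeated-measures ANOVA."""

    per_subject: pd.DataFrame  # subject, mean_cm, sd_cm, n_used
    anova_f: float
    df1: float
    df2: float
    p_value: float
    gg_epsilon: float

    @property
    def grand_mean(self) -> float:
        return float(self.per_subject["mean_cm"].mean())

    @property
    def between_subject_sd(self) -> float:
        return float(self.per_subject["mean_cm"].std(ddof=1))


def sdp_summary(trials: list[SDPTrials]) -> SDPSummary:
    """Summarize stop-distance trials across subjects.

    The leading warm-up trial of each subject is excluded, then a one-way
    repeated-measures ANOVA (trial number as the within factor) is run with
    Greenhouse-Geisser sphericity correction; corrected degrees of freedom are
    reported. A null trial effect (stable distances over repetitions) is the
    expected outcome.
    """
    import pingouin as pg

    rows = []
    long_rows = []
    for t in trials:
        usable = t.usable()
        if len(usable) < 2:
            raise ValueError(f"subject {t.subject}: fewer than 2 usable trials")
        rows.append({
            "subject": t.subject,
            "mean_cm": float(np.mean(usable)),
            "sd_cm": float(np.std(usable, ddof=1)),
            "n_used": len(usable),
        })
        for i, d in enumerate(usable):
            long_rows.append({"subject": t.subject, "trial": i + 1,
                              "distance": float(d)})
    per_subject = pd.DataFrame(rows)
    long = pd.DataFrame(long_rows)

    if per_subject.shape[0] < 2:
        # a single subject cannot support the across-subject trial ANOVA
        return SDPSummary(per_subject=per_subject, anova_f=np.nan,
                          df1=np.nan, df2=np.nan, p_value=np.nan,
                          gg_epsilon=np.nan)

    if long.groupby("subject")["distance"].std(ddof=0).max() == 0:
        # no within-subject variance at all: trial effect is exactly null
        k = long["trial"].nunique()
        n = per_subject.shape[0]
        return SDPSummary(per_subject=per_subject, anova_f=0.0,
                          df1=float(k - 1), df2=float((k - 1) * (n - 1)),
                          p_value=1.0, gg_epsilon=1.0)

    aov = pg.rm_anova(data=long, dv="distance", within="trial",
                      subject="subject", correction=False, detailed=True)
    trial_row = aov.loc[aov["Source"] == "trial"].iloc[0]
    error_row = aov.loc[aov["Source"] == "Error"].iloc[0]
    f = float(trial_row["F"])
    wide = long.pivot(index="subject", columns="trial", values="distance")
    eps = _gg_epsilon(wide.to_numpy())
    df1 = float(trial_row["DF"]) * eps
    df2 = float(error_row["DF"]) * eps
    p = float(stats.f.sf(f, df1, df2))
    return SDPSummary(per_subject=per_subject, anova_f=f, df1=df1, df2=df2,
                      p_value=p, gg_epsilon=eps)


def _gg_epsilon(data: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the trial covariance matrix.

    ``data`` is subjects x trials; epsilon = tr(C)^2 / ((k-1) tr(C^2)) with C
    the double-centered covariance of the k repeated measures. Bounded in
    [1/(k-1), 1].
    """
    k = data.shape[1]
    s = np.cov(data, rowvar=False, ddof=1)
    h = np.eye(k) - np.ones((k, k)) / k
    c = h @ s @ h
    denom = (k - 1) * np.trace(c @ c)
    if denom <= 0:
        return 1.0
    eps = np.trace(c) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))
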