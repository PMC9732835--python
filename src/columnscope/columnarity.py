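"""Depth-resolved map sampling and radial-vs-tangential correlation statistics.

A columnar (radially uniform) functional organization predicts that activity
maps sampled at different cortical depths correlate strongly with each other
(within-column, radial axis), while maps compared across a comparable lateral
offset (surface-parallel axis) correlate weakly. A second control compares
maps inside the gray matter against planes sampled above the pia, where only
vessel-driven structure lives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import Volume


def sample_depth_map(
    volume: Volume,
    frac: float | None = None,
    mm: float | None = None,
) -> np.ndarray:
    """Sample a lateral map at one depth by linear interpolation.

    Exactly one of ``frac`` (fractional depth within the gray matter,
    converted per (x, y) through the local thickness) or ``mm`` (absolute
    position on the depth axis; negative = above the pia) must be given.
    """
    if (frac is None) == (mm is None):
        raise ValueError("give exactly one of frac or mm")
    sheet = volume.sheet
    axis = sheet.depth_axis
    if frac is not None:
        pos = sheet.frac_to_mm(frac)
    else:
        pos = np.full(sheet.shape, float(mm))
    if np.any(pos < axis[0] - 1e-9) or np.any(pos > axis[-1] + 1e-9):
        raise ValueError("requested depth lies outside the sampled depth axis")
    pos = np.clip(pos, axis[0], axis[-1])
    idx = np.clip(np.searchsorted(axis, pos) - 1, 0, len(axis) - 2)
    lo = axis[idx]
    hi = axis[idx + 1]
    w = (pos - lo) / (hi - lo)
    yy, xx = np.ogrid[0:sheet.ny, 0:sheet.nx]
    return (1 - w) * volume.data[yy, xx, idx] + w * volume.data[yy, xx, idx + 1]


@dataclass
class DepthStack:
    """Lateral maps at requested depth positions.

    Keys are ``("frac", f)`` for fractional within-gray depths and
    ``("mm", d)`` for absolute positions (negative above the pia).
    """

    maps: dict[tuple[str, float], np.ndarray]
    positions: list[tuple[str, float]]

    def get(self, kind: str, value: float) -> np.ndarray:
        return self.maps[(kind, float(value))]


def build_depth_stack(
    volume: Volume,
    fracs: tuple[float, ...] = (0.1, 0.5, 0.9),
    mms: tuple[float, ...] = (),
) -> DepthStack:
    maps: dict[tuple[str, float], np.ndarray] = {}
    positions: list[tuple[str, float]] = []
    for f in fracs:
        maps[("frac", float(f))] = sample_depth_map(volume, frac=f)
        positions.append(("frac", float(f)))
    for d in mms:
        maps[("mm", float(d))] = sample_depth_map(volume, mm=d)
        positions.append(("mm", float(d)))
    return DepthStack(maps=maps, positions=positions)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("correlation undefined for a constant map")
    return float(np.corrcoef(a, b)[0, 1])


def shifted_correlation(
    map_: np.ndarray,
    lateral_offset_mm: float,
    dx: float,
    roi: np.ndarray | None = None,
) -> float:
    """Lateral-shift autocorrelation, averaged over the four axis directions.

    The map is compared against copies of itself shifted by the offset along
    +x, -x, +y and -y; vertices whose shifted partner leaves the grid (or the
    ROI) are dropped pairwise.
    """
    k = int(round(lateral_offset_mm / dx))
    if k < 1:
        raise ValueError("lateral offset must be at least the grid spacing")
    rs = []
    for dy_, dx_ in ((0, k), (0, -k), (k, 0), (-k, 0)):
        src_y = slice(max(0, -dy_), map_.shape[0] - max(0, dy_))
        src_x = slice(max(0, -dx_), map_.shape[1] - max(0, dx_))
        dst_y = slice(max(0, dy_), map_.shape[0] - max(0, -dy_))
        dst_x = slice(max(0, dx_), map_.shape[1] - max(0, -dx_))
        a = map_[src_y, src_x]
        b = map_[dst_y, dst_x]
        if roi is not None:
            keep = roi[src_y, src_x] & roi[dst_y, dst_x]
            a, b = a[keep], b[keep]
        rs.append(_pearson(a, b))
    return float(np.mean(rs))


@dataclass
class AxisCorrStats:
    """Radial vs surface-parallel correlations for one subject."""

    r_within: float
    r_across_deep: float
    r_across_superficial: float

    def as_row(self, subject: str = "") -> dict[str, float | str]:
        return {
            "subject": subject,
            "r_within": self.r_within,
            "r_across_deep": self.r_across_deep,
            "r_across_superficial": self.r_across_superficial,
        }


def axis_correlations(
    superficial_map: np.ndarray,
    deep_map: np.ndarray,
    lateral_offset_mm: float,
    dx: float,
    roi: np.ndarray | None = None,
) -> AxisCorrStats:
    """Within-column vs across-column correlations for one subject.

    ``r_within`` correlates the superficial (fractional depth 0.1) and deep
    (0.9) maps vertex by vertex; the across-column values are lateral-shift
    autocorrelations of each map at ``lateral_offset_mm`` (matched to the mean
    radial separation of the two depths, ~0.8 x mean thickness).
    """
    if roi is not None:
        r_within = _pearson(superficial_map[roi], deep_map[roi])
    else:
        r_within = _pearson(superficial_map, deep_map)
    return AxisCorrStats(
        r_within=r_within,
        r_across_deep=shifted_correlation(deep_map, lateral_offset_mm, dx, roi),
        r_across_superficial=shifted_correlation(
            superficial_map, lateral_offset_mm, dx, roi),
    )


def vessel_control_correlations(
    deep_map: np.ndarray,
    surface_map: np.ndarray,
    above_maps: dict[float, np.ndarray],
) -> dict[str, float]:
    """Deep-layer map vs the surface and vs above-pia planes (one subject).

    Column "A" is the within-gray reference (deep vs surface); the remaining
    columns correlate the deep map against planes sampled above the pia.
    """
    out = {"A": _pearson(deep_map, surface_map)}
    for name, h in zip("BCD", sorted(above_maps)):
        out[name] = _pearson(deep_map, above_maps[h])
    return out


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher's variance-stabilizing transformation, z = atanh(r)."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for the Fisher transformation")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    """Paired t test: t = mean(a-b) / (sd(a-b)/sqrt(n)), df = n-1, 2-sided p.

    With zero variance of the differences, t is reported as +/-inf (p = 0)
    for a nonzero mean difference and 0 (p = 1) when a equals b.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def axis_correlation_table(
    rows: list[AxisCorrStats],
    subjects: list[str] | None = None,
    use_fisher_z: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject axis correlations plus paired comparisons.

    The radial (within-column) correlations are compared against each
    surface-parallel column with paired t tests, after Fisher z
    transformation by default (set ``use_fisher_z=False`` to test raw r).
    Returns (per-subject table, test table).
    """
    if subjects is None:
        subjects = [f"s{i + 1}" for i in range(len(rows))]
    table = pd.DataFrame([r.as_row(s) for r, s in zip(rows, subjects)])
    if len(rows) < 2:
        return table, pd.DataFrame(
            columns=["comparison", "t", "df", "p", "fisher_z"])
    tests = []
    within = table["r_within"].to_numpy()
    for col, label in (("r_across_deep", "within_vs_across_deep"),
                       ("r_across_superficial", "within_vs_across_superficial")):
        other = table[col].to_numpy()
        if use_fisher_z:
            t, df, p = paired_t(fisher_z(within), fisher_z(other))
        else:
            t, df, p = paired_t(within, other)
        tests.append({"comparison": label, "t": t, "df": df, "p": p,
                      "fisher_z": use_fisher_z})
    return table, pd.DataFrame(tests)


def vessel_control_table(
    rows: list[dict[str, float]],
    subjects: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gray-matter vs above-surface correlation table plus paired t tests.

    Column A (deep vs surface, within gray) is tested against each
    above-surface column B-D on the raw correlation values.
    """
    if subjects is None:
        subjects = [f"s{i + 1}" for i in range(len(rows))]
    table = pd.DataFrame(rows, index=subjects)
    if len(rows) < 2:
        return table, pd.DataFrame(columns=["comparison", "t", "df", "p"])
    tests = []
    a = table["A"].to_numpy()
    for col in [c for c in table.columns if c != "A"]:
        t, df, p = paired_t(a, table[col].to_numpy())
        tests.append({"comparison": f"A_vs_{col}", "t": t, "df": df, "p": p})
    return table, pd.DataFrame(tests)
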