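"""Synthetic laminar cortex, BOLD runs, and stop-distance behavior.

This module generates the ground truth the rest of the package analyzes: a
flattened gray-matter slab carrying radially uniform, laterally interdigitated
column families (P: approach/withdrawal poles; D: near/far disparity poles), a
surface-parallel "vessel" pattern confined above the pia, block- and
event-designed BOLD time series at TR = 3 s, and behavioral stop-distance
trials.

Depth convention: depth is measured in mm from the pia. 0 = pia, positive
depths run through the gray matter down to the gray/white interface at the
local thickness; negative depths lie above the pia (pial/vessel space).
Fractional depth = mm / local thickness, so fraction 0.0 is the pia and 1.0
the gray/white interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import truncnorm

logger = logging.getLogger(__name__)

#: integer codes for the column families: P columns prefer approaching (PA) or
#: withdrawing (PW) faces; D columns prefer near (DN) or far (DF) disparity.
LABEL_CODES = {"none": 0, "PA": 1, "PW": 2, "DN": 3, "DF": 4}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}
COLUMN_LABELS = ("PA", "PW", "DN", "DF")

#: mean gray-matter thickness (mm) of the parietal region being emulated.
DEFAULT_THICKNESS_MM = 2.37
#: repetition time of the emulated acquisitions (s).
DEFAULT_TR_S = 3.0


@dataclass
class LaminarSheet:
    """Geometry of a flattened cortical patch.

    Parameters
    ----------
    nx, ny : int
        Lateral grid size (vertices).
    dx : float
        Lateral vertex spacing in mm.
    thickness : ndarray, shape (ny, nx)
        Local gray-matter thickness in mm (strictly positive).
    depth_axis : ndarray
        Sampled depth positions in mm, strictly increasing; negative values
        lie above the pia, 0 is the pia.
    """

    nx: int
    ny: int
    dx: float
    thickness: np.ndarray
    depth_axis: np.ndarray

    def __post_init__(self) -> None:
        self.thickness = np.asarray(self.thickness, dtype=float)
        self.depth_axis = np.asarray(self.depth_axis, dtype=float)
        if self.thickness.shape != (self.ny, self.nx):
            raise ValueError("thickness must have shape (ny, nx)")
        if not np.all(self.thickness > 0):
            raise ValueError("thickness must be positive everywhere")
        if not np.all(np.diff(self.depth_axis) > 0):
            raise ValueError("depth_axis must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def frac_to_mm(self, frac: float) -> np.ndarray:
        """Convert a fractional depth to per-(x, y) positions in mm."""
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fractional depth must lie in [0, 1]")
        return frac * self.thickness


def default_depth_axis(
    max_above_mm: float = 2.4,
    max_below_mm: float = DEFAULT_THICKNESS_MM,
    n_above: int = 4,
    n_below: int = 8,
) -> np.ndarray:
    """Depth axis spanning above-surface offsets through the gray matter."""
    above = np.linspace(-max_above_mm, 0.0, n_above, endpoint=False)
    below = np.linspace(0.0, max_below_mm, n_below)
    return np.concatenate([above, below])


def make_sheet(
    nx: int = 128,
    ny: int = 128,
    dx: float = 0.5,
    mean_thickness: float = DEFAULT_THICKNESS_MM,
    thickness_sd: float = 0.0,
    depth_axis: np.ndarray | None = None,
    seed: int | None = None,
) -> LaminarSheet:
    """Build a flattened slab with (optionally jittered) thickness."""
    rng = np.random.default_rng(seed)
    thickness = np.full((ny, nx), mean_thickness)
    if thickness_sd > 0:
        thickness = thickness + rng.normal(0.0, thickness_sd, size=(ny, nx))
        thickness = np.clip(thickness, 0.5 * mean_thickness, None)
    if depth_axis is None:
        depth_axis = default_depth_axis(max_below_mm=float(np.max(thickness)))
    return LaminarSheet(nx=nx, ny=ny, dx=dx, thickness=thickness,
                        depth_axis=np.asarray(depth_axis, float))


@dataclass
class ColumnLabelMap:
    """Per-(x, y) ground-truth column labels (constant along depth)."""

    labels: np.ndarray  # (ny, nx) int codes, see LABEL_CODES
    centers: pd.DataFrame  # columns: label, cy, cx (grid units), radius_mm
    dx: float
    seed: int | None = None

    def mask(self, label: str) -> np.ndarray:
        return self.labels == LABEL_CODES[label]

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class VesselLayer:
    """Surface-parallel scalar pattern with support strictly above the pia."""

    pattern: np.ndarray  # (ny, nx)
    seed: int | None = None


def plant_columns(
    sheet: LaminarSheet,
    density_per_cm2: dict[str, float] | float = 0.7,
    radius_range_mm: tuple[float, float] = (1.2, 2.0),
    min_gap_mm: float = 0.5,
    seed: int | None = None,
    max_tries_per_column: int = 2000,
) -> ColumnLabelMap:
    """Plant disjoint quasi-round columns of all four families by dart throwing.

    Centers are drawn uniformly; a candidate is rejected when its disc (plus
    ``min_gap_mm``) would touch an existing column. Labels are assigned
    round-robin over PA, DN, PW, DF so the P and D families interleave
    laterally. The same seed always yields the same map.

    Raises
    ------
    RuntimeError
        If the requested density cannot be packed after bounded retries.
    """
    rng = np.random.default_rng(seed)
    area_cm2 = sheet.nx * sheet.ny * sheet.dx**2 / 100.0
    if not isinstance(density_per_cm2, dict):
        density_per_cm2 = {lab: float(density_per_cm2) for lab in COLUMN_LABELS}
    counts = {lab: int(round(density_per_cm2.get(lab, 0.0) * area_cm2))
              for lab in COLUMN_LABELS}
    r_lo, r_hi = radius_range_mm
    if r_lo <= sheet.dx:
        raise ValueError("column radii must exceed the grid spacing dx")

    # round-robin order interleaves the two families
    order: list[str] = []
    remaining = dict(counts)
    cycle = ("PA", "DN", "PW", "DF")
    while any(v > 0 for v in remaining.values()):
        for lab in cycle:
            if remaining[lab] > 0:
                order.append(lab)
                remaining[lab] -= 1

    labels = np.zeros(sheet.shape, dtype=np.int8)
    yy, xx = np.mgrid[0:sheet.ny, 0:sheet.nx]
    placed: list[tuple[float, float, float]] = []  # (cy, cx, r) in mm
    rows = []
    for lab in order:
        r = rng.uniform(r_lo, r_hi)
        for _ in range(max_tries_per_column):
            cy = rng.uniform(0, sheet.ny) * sheet.dx
            cx = rng.uniform(0, sheet.nx) * sheet.dx
            ok = all(np.hypot(cy - py, cx - px) >= r + pr + min_gap_mm
                     for py, px, pr in placed)
            if ok:
                placed.append((cy, cx, r))
                disc = (yy * sheet.dx - cy) ** 2 + (xx * sheet.dx - cx) ** 2 <= r**2
                labels[disc] = LABEL_CODES[lab]
                rows.append({"label": lab, "cy": cy / sheet.dx,
                             "cx": cx / sheet.dx, "radius_mm": r})
                break
        else:
            raise RuntimeError(
                f"could not pack {sum(counts.values())} columns "
                f"(failed after {len(placed)} placements); lower the density "
                "or radii"
            )
    centers = pd.DataFrame(rows, columns=["label", "cy", "cx", "radius_mm"])
    return ColumnLabelMap(labels=labels, centers=centers, dx=sheet.dx, seed=seed)


def make_vessel_layer(
    sheet: LaminarSheet,
    smooth_mm: float = 2.0,
    amplitude: float = 1.0,
    decorrelate_from: np.ndarray | None = None,
    seed: int | None = None,
) -> VesselLayer:
    """Smooth random surface-parallel pattern, optionally orthogonalized.

    The pattern emulates hemodynamic structure above the pia (large vessels)
    that is spatially unrelated to the columnar map. When ``decorrelate_from``
    is given the pattern is regressed against it so the sample correlation is
    exactly zero.
    """
    rng = np.random.default_rng(seed)
    raw = rng.standard_normal(sheet.shape)
    pattern = ndimage.gaussian_filter(raw, sigma=smooth_mm / sheet.dx, mode="wrap")
    pattern = pattern - pattern.mean()
    sd = pattern.std()
    if sd > 0:
        pattern = pattern / sd
    if decorrelate_from is not None:
        ref = np.asarray(decorrelate_from, float) - np.mean(decorrelate_from)
        denom = float(np.sum(ref * ref))
        if denom > 0:
            pattern = pattern - (np.sum(pattern * ref) / denom) * ref
    return VesselLayer(pattern=amplitude * pattern, seed=seed)


@dataclass
class Volume:
    """3-D scalar field over a flattened cortical patch."""

    sheet: LaminarSheet
    data: np.ndarray  # (ny, nx, n_depth) aligned with sheet.depth_axis

    def __post_init__(self) -> None:
        expected = (self.sheet.ny, self.sheet.nx, len(self.sheet.depth_axis))
        if self.data.shape != expected:
            raise ValueError(f"data must have shape {expected}")


def render_volume(
    labels: ColumnLabelMap,
    sheet: LaminarSheet,
    amplitudes: dict[str, float],
    vessel: VesselLayer | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Volume:
    """Render a condition-contrast volume with radially uniform columns.

    Within the gray matter (0 <= depth <= local thickness) the expected value
    at (x, y, d) is ``amplitudes[label(x, y)]`` independent of depth; above the
    pia it equals the vessel pattern; below the gray/white interface it is 0.
    Independent Gaussian noise (sd ``noise_sd``) is added per voxel.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    amp_map = np.zeros(sheet.shape)
    for lab, amp in amplitudes.items():
        if not np.isfinite(amp):
            raise ValueError("amplitudes must be finite")
        amp_map[labels.labels == LABEL_CODES[lab]] = amp
    depth = sheet.depth_axis
    data = np.zeros(sheet.shape + (len(depth),))
    in_gray = (depth[None, None, :] >= 0) & (
        depth[None, None, :] <= sheet.thickness[:, :, None]
    )
    data += amp_map[:, :, None] * in_gray
    if vessel is not None:
        above = depth[None, None, :] < 0
        data += vessel.pattern[:, :, None] * above
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data += rng.normal(0.0, noise_sd, size=data.shape)
    return Volume(sheet=sheet, data=data)


# ---------------------------------------------------------------------------
# BOLD run simulation
# ---------------------------------------------------------------------------

@dataclass
class BoldRun:
    """One simulated BOLD run on a lateral grid at a single depth plane."""

    tr: float
    series: np.ndarray  # (n_timepoints, ny, nx)
    events: pd.DataFrame  # columns: onset, duration, condition
    motion: np.ndarray  # (n_timepoints, 6)
    seed: int | None = None

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def duration(self) -> float:
        return self.n_timepoints * self.tr

    def flat_series(self) -> np.ndarray:
        """Series reshaped to (n_timepoints, n_vertices)."""
        return self.series.reshape(self.n_timepoints, -1)


def _events_frame(rows: list[tuple[float, float, str]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["onset", "duration", "condition"])


def block_design(
    conditions: tuple[str, str] = ("approach", "withdrawal"),
    n_stim_blocks: int = 16,
    block_s: float = 15.0,
    blank_s: float = 15.0,
    tr: float = DEFAULT_TR_S,
    seed: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Alternating-condition block design bracketed by two blank displays.

    The default (16 stimulus blocks of 15 s plus leading and trailing 15-s
    blanks) fills exactly 90 TRs at TR = 3 s. Block order within condition
    pairs is pseudorandomized.
    """
    rng = np.random.default_rng(seed)
    seq: list[str] = []
    for _ in range(n_stim_blocks // 2):
        pair = list(conditions)
        rng.shuffle(pair)
        seq.extend(pair)
    if n_stim_blocks % 2:
        seq.append(conditions[rng.integers(2)])
    rows = []
    t = blank_s
    for cond in seq:
        rows.append((t, block_s, cond))
        t += block_s
    total_s = t + blank_s
    n_timepoints = int(round(total_s / tr))
    if not np.isclose(n_timepoints * tr, total_s):
        raise ValueError("design duration is not a whole number of TRs")
    return _events_frame(rows), n_timepoints


def disparity_block_design(
    conditions: tuple[str, str] = ("near", "far"),
    n_stim_blocks: int = 8,
    block_s: float = 24.0,
    blank_s: float = 12.0,
    n_timepoints: int = 80,
    tr: float = DEFAULT_TR_S,
    seed: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Disparity block design: 8 x 24-s blocks bracketed by 12-s blanks.

    8*24 + 2*12 = 216 s, which is short of the nominal 80 TRs (240 s); the
    final blank is padded to fill the run, and the padding is logged.
    """
    rng = np.random.default_rng(seed)
    seq: list[str] = []
    for _ in range(n_stim_blocks // 2):
        pair = list(conditions)
        rng.shuffle(pair)
        seq.extend(pair)
    if n_stim_blocks % 2:
        seq.append(conditions[rng.integers(2)])
    rows = []
    t = blank_s
    for cond in seq:
        rows.append((t, block_s, cond))
        t += block_s
    nominal = t + blank_s
    run_s = n_timepoints * tr
    if run_s < nominal:
        raise ValueError("design overruns the requested run length")
    if run_s > nominal:
        logger.info(
            "disparity design: padding final blank by %.0f s to fill %d TRs",
            run_s - nominal, n_timepoints,
        )
    return _events_frame(rows), n_timepoints


def event_design(
    conditions: list[str],
    n_events_per_condition: int = 4,
    event_s: float = 3.0,
    iti_range_s: tuple[float, float] = (3.0, 12.0),
    tr: float = DEFAULT_TR_S,
    lead_in_s: float = 6.0,
    lead_out_s: float = 12.0,
    seed: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Pseudorandomized event-related design (3-s events, jittered ITI).

    ITIs are drawn uniformly from the TR-aligned values within
    ``iti_range_s``. Returns the event table and the number of TRs needed.
    """
    rng = np.random.default_rng(seed)
    seq = [c for c in conditions for _ in range(n_events_per_condition)]
    rng.shuffle(seq)
    iti_choices = np.arange(iti_range_s[0], iti_range_s[1] + 0.5 * tr, tr)
    rows = []
    t = lead_in_s
    for cond in seq:
        rows.append((t, event_s, cond))
        t += event_s + float(rng.choice(iti_choices))
    total_s = t + lead_out_s
    n_timepoints = int(np.ceil(total_s / tr))
    return _events_frame(rows), n_timepoints


def simulate_bold_run(
    labels: ColumnLabelMap,
    events: pd.DataFrame,
    n_timepoints: int,
    amplitudes: dict[str, dict[str, float]],
    hrf: np.ndarray | None = None,
    tr: float = DEFAULT_TR_S,
    baseline: float = 100.0,
    drift_coeffs: tuple[float, ...] = (0.0, 0.0, 0.0),
    noise_sd: float = 1.0,
    spikes: list[tuple[int, float]] | None = None,
    amplitude_pattern: np.ndarray | None = None,
    motion_sd: float = 0.05,
    seed: int | None = None,
) -> BoldRun:
    """Simulate one BOLD run over the lateral grid.

    series = baseline + sum_c amp_map_c * (boxcar_c (x) hrf) + drift + noise
    (+ optional additive spikes at given TRs). ``amplitudes`` maps condition ->
    {label -> amplitude}; vertices whose label is missing get 0. When
    ``amplitude_pattern`` is given (e.g., a vessel pattern for an above-pia
    plane), each condition's amplitude map is ``amplitudes[cond].get('pattern',
    0) * amplitude_pattern`` added on top of the label-driven map.

    Raises
    ------
    ValueError
        If any event extends past the end of the run.
    """
    from .glm import canonical_hrf  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    run_s = n_timepoints * tr
    if np.any(events["onset"] + events["duration"] > run_s + 1e-9):
        raise ValueError("design overruns the run length")
    if hrf is None:
        hrf = canonical_hrf(tr)
    ny, nx = labels.shape
    series = np.full((n_timepoints, ny, nx), float(baseline))

    frame_times = np.arange(n_timepoints) * tr
    for cond in events["condition"].unique():
        boxcar = np.zeros(n_timepoints)
        for _, ev in events[events["condition"] == cond].iterrows():
            i0 = int(np.floor(ev["onset"] / tr))
            i1 = int(np.ceil((ev["onset"] + ev["duration"]) / tr))
            boxcar[i0:min(i1, n_timepoints)] = 1.0
        reg = np.convolve(boxcar, hrf)[:n_timepoints]
        amp_map = np.zeros((ny, nx))
        for lab, amp in amplitudes.get(cond, {}).items():
            if lab == "pattern":
                continue
            amp_map[labels.labels == LABEL_CODES[lab]] = amp
        if amplitude_pattern is not None:
            amp_map = amp_map + (
                amplitudes.get(cond, {}).get("pattern", 0.0) * amplitude_pattern
            )
        series += reg[:, None, None] * amp_map[None, :, :]

    if any(c != 0 for c in drift_coeffs):
        x = np.linspace(-1, 1, n_timepoints)
        drift = sum(c * np.polynomial.legendre.Legendre.basis(k)(x)
                    for k, c in enumerate(drift_coeffs))
        series += np.asarray(drift)[:, None, None]
    if noise_sd > 0:
        series += rng.normal(0.0, noise_sd, size=series.shape)
    if spikes:
        for t_idx, magnitude in spikes:
            if not 0 <= t_idx < n_timepoints:
                raise ValueError("spike index outside the run")
            series[t_idx] += magnitude
    motion = np.cumsum(rng.normal(0.0, motion_sd, size=(n_timepoints, 6)), axis=0)
    _ = frame_times  # onsets validated above; kept for clarity
    return BoldRun(tr=tr, series=series, events=events.copy(), motion=motion,
                   seed=seed)


# ---------------------------------------------------------------------------
# Behavior: stop-distance trials
# ---------------------------------------------------------------------------

@dataclass
class SDPTrials:
    """Stop-distance trials for one subject, in presentation order."""

    subject: str
    trials: np.ndarray  # cm, warm-up first when flagged
    warm_up_included: bool = True

    def usable(self) -> np.ndarray:
        """Trials after excluding the leading warm-up trial."""
        return self.trials[1:] if self.warm_up_included else self.trials


def simulate_sdp_trials(
    mean_cm: float = 57.0,
    sd_cm: float = 11.3,
    n_trials: int = 5,
    subject: str = "s1",
    seed: int | None = None,
) -> SDPTrials:
    """Draw i.i.d. positive stop distances plus one leading warm-up trial.

    Distances are truncated-normal at 0 so they stay positive; the defaults
    match the behavioral summary of the emulated study (mean 57 cm, SD
    11.3 cm). The warm-up trial is drawn from the same distribution and
    flagged for exclusion.
    """
    if mean_cm <= 0:
        raise ValueError("mean stop distance must be positive")
    if n_trials < 2:
        raise ValueError("need at least two trials")
    rng = np.random.default_rng(seed)
    if sd_cm == 0:
        draws = np.full(n_trials + 1, mean_cm)
    else:
        a = (0.0 - mean_cm) / sd_cm
        draws = truncnorm.rvs(a, np.inf, loc=mean_cm, scale=sd_cm,
                              size=n_trials + 1, random_state=rng)
    return SDPTrials(subject=subject, trials=np.asarray(draws),
                     warm_up_included=True)
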