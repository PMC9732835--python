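"""First-level GLM: canonical HRF, design construction, DVARS scrubbing,
ordinary-least-squares fitting, and signed contrast maps.

Condition regressors are boxcars convolved with the canonical double-gamma
hemodynamic response; nuisance columns hold motion traces, per-timepoint spike
indicators for DVARS-flagged frames, and Legendre drift polynomials. Contrast
maps carry the signed -log10(p) convention: positive where the first condition
is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy import stats


def canonical_hrf(
    dt: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    ratio: float = 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt`` seconds, unit peak.

    The response is a gamma density peaking near ``peak_delay`` (~5-6 s) minus
    an undershoot gamma peaking near ``undershoot_delay``, scaled by
    1/``ratio``, over ``length`` seconds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0, length + dt / 2, dt)

    def gamma_pdf(t, shape, scale):
        with np.errstate(divide="ignore"):
            logpdf = ((shape - 1) * np.log(np.maximum(t, 1e-300))
                      - t / scale - gammaln(shape) - shape * np.log(scale))
        out = np.exp(logpdf)
        out[t <= 0] = 0.0
        return out

    response = gamma_pdf(t, peak_delay / dispersion, dispersion)
    undershoot = gamma_pdf(t, undershoot_delay / undershoot_dispersion,
                           undershoot_dispersion)
    hrf = response - undershoot / ratio
    return hrf / hrf.max()


@dataclass
class DesignMatrix:
    """Named design matrix for one run."""

    matrix: np.ndarray  # (n_timepoints, n_regressors)
    names: list[str]
    condition_names: list[str]

    @property
    def n_timepoints(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> int:
        return self.names.index(name)

    def condition_contrast(self, a: str, b: str | None = None) -> np.ndarray:
        """Contrast vector for condition ``a`` (minus ``b`` if given)."""
        c = np.zeros(self.matrix.shape[1])
        c[self.column(f"cond:{a}")] += 1.0
        if b is not None:
            c[self.column(f"cond:{b}")] -= 1.0
        return c


def build_design_matrix(
    events: pd.DataFrame,
    n_timepoints: int,
    tr: float,
    hrf: np.ndarray | None = None,
    motion: np.ndarray | None = None,
    spike_flags: np.ndarray | None = None,
    drift_order: int = 2,
    oversample: int = 1,
) -> DesignMatrix:
    """Assemble condition, nuisance, spike, and drift regressors.

    Condition boxcars are built at ``tr/oversample`` resolution, convolved
    with the HRF, and downsampled to the TR grid; ``oversample > 1`` handles
    onsets that do not align with TRs (the designs in this package are
    TR-aligned, so the default works on the TR grid directly). Drift uses
    Legendre polynomials up to ``drift_order`` (order 0 is the intercept).
    Raises if the result is rank deficient.
    """
    dt = tr / oversample
    if hrf is None:
        hrf = canonical_hrf(dt)
    elif oversample != 1 and len(hrf) < n_timepoints:
        # caller supplied a TR-sampled kernel; rebuild at the fine grid
        hrf = np.interp(np.arange(0, (len(hrf) - 1) * tr + dt / 2, dt),
                        np.arange(len(hrf)) * tr, hrf)
    n_fine = n_timepoints * oversample
    cols: list[np.ndarray] = []
    names: list[str] = []
    condition_names = list(pd.unique(events["condition"]))
    for cond in condition_names:
        boxcar = np.zeros(n_fine)
        for _, ev in events[events["condition"] == cond].iterrows():
            i0 = int(round(ev["onset"] / dt))
            i1 = int(round((ev["onset"] + ev["duration"]) / dt))
            boxcar[i0:min(i1, n_fine)] = 1.0
        # divide by oversample so the regressor amplitude matches a TR-grid
        # convolution with the same unit-peak kernel
        reg = np.convolve(boxcar, hrf)[:n_fine][::oversample] / oversample
        cols.append(reg)
        names.append(f"cond:{cond}")
    if motion is not None:
        motion = np.asarray(motion, float)
        demeaned = motion - motion.mean(axis=0)
        for j in range(demeaned.shape[1]):
            cols.append(demeaned[:, j])
            names.append(f"motion:{j}")
    if spike_flags is not None:
        for t_idx in np.flatnonzero(np.asarray(spike_flags, bool)):
            ind = np.zeros(n_timepoints)
            ind[t_idx] = 1.0
            cols.append(ind)
            names.append(f"spike:{t_idx}")
    x = np.linspace(-1, 1, n_timepoints)
    for k in range(drift_order + 1):
        cols.append(np.asarray(np.polynomial.legendre.Legendre.basis(k)(x)))
        names.append(f"drift:{k}")
    matrix = np.column_stack(cols)
    rank = np.linalg.matrix_rank(matrix)
    if rank < matrix.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < "
            f"{matrix.shape[1]}); collinear columns among: "
            + ", ".join(_collinear_columns(matrix, names))
        )
    return DesignMatrix(matrix=matrix, names=names,
                        condition_names=condition_names)


def _collinear_columns(matrix: np.ndarray, names: list[str]) -> list[str]:
    """Name columns fully explained by the others (R^2 ~ 1)."""
    bad = []
    for j in range(matrix.shape[1]):
        others = np.delete(matrix, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, matrix[:, j], rcond=None)
        resid = matrix[:, j] - others @ beta
        denom = np.sum((matrix[:, j] - matrix[:, j].mean()) ** 2)
        if denom == 0 or np.sum(resid**2) / max(denom, 1e-300) < 1e-10:
            bad.append(names[j])
    return bad or names


@dataclass
class QCTrace:
    """DVARS per timepoint with the boxplot outlier rule applied."""

    dvars: np.ndarray  # (n_timepoints,), NaN at t = 0 (undefined)
    threshold: float
    flags: np.ndarray  # bool, never True at t = 0


def dvars_outliers(series: np.ndarray) -> QCTrace:
    """DVARS scrubbing: flag frames with excessive whole-volume signal change.

    DVARS_t is the RMS over voxels of the frame-to-frame difference; frames
    with DVARS above Q3 + 1.5 * IQR (computed over the defined frames) are
    flagged as outliers. The first frame has no DVARS and is never flagged.

    Parameters
    ----------
    series : ndarray, (n_timepoints, n_voxels) or (n_timepoints, ny, nx)
    """
    series = np.asarray(series, float)
    series = series.reshape(series.shape[0], -1)
    if series.shape[0] < 2:
        raise ValueError("DVARS needs at least two timepoints")
    diffs = np.diff(series, axis=0)
    dvars_defined = np.sqrt(np.mean(diffs**2, axis=1))
    dvars = np.concatenate([[np.nan], dvars_defined])
    q1, q3 = np.percentile(dvars_defined, [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    flags = np.zeros(series.shape[0], dtype=bool)
    flags[1:] = dvars_defined > threshold
    return QCTrace(dvars=dvars, threshold=float(threshold), flags=flags)


@dataclass
class GLMFit:
    """OLS fit of one design to a (flattened) ensemble of vertex series."""

    betas: np.ndarray  # (n_regressors, n_vertices)
    sigma2: np.ndarray  # (n_vertices,) residual variance at df
    df: int
    design: DesignMatrix
    grid_shape: tuple[int, int] | None = None


def fit_glm(series: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Ordinary least squares per vertex.

    Spike-indicator columns in the design absorb their timepoints exactly, so
    flagged frames have no influence on the condition betas; their timepoints
    are also excluded from the residual degrees of freedom.
    """
    series = np.asarray(series, float)
    grid_shape = series.shape[1:] if series.ndim == 3 else None
    y = series.reshape(series.shape[0], -1)
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError("series and design disagree on n_timepoints")
    betas, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < x.shape[1]:
        raise ValueError(
            "design matrix is rank deficient; collinear columns among: "
            + ", ".join(_collinear_columns(x, design.names)))
    resid = y - x @ betas
    df = x.shape[0] - x.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.sum(resid**2, axis=0) / df
    return GLMFit(betas=betas, sigma2=sigma2, df=df, design=design,
                  grid_shape=grid_shape)


@dataclass
class ContrastMap:
    """Signed vertex-wise contrast statistics.

    ``signed_logp`` is -log10(p) carrying the sign of the contrast estimate:
    positive where the first condition of the contrast is preferred.
    """

    beta: np.ndarray
    t: np.ndarray
    p: np.ndarray
    signed_logp: np.ndarray
    name: str = ""

    def reshape(self, shape: tuple[int, int]) -> "ContrastMap":
        return ContrastMap(
            beta=self.beta.reshape(shape), t=self.t.reshape(shape),
            p=self.p.reshape(shape), signed_logp=self.signed_logp.reshape(shape),
            name=self.name)


def contrast_map(fit: GLMFit, contrast: np.ndarray, name: str = "") -> ContrastMap:
    """t test of a contrast of betas, per vertex, with signed -log10 p.

    t = c'beta / se(c'beta); two-sided p from the t distribution at the
    residual df. p is floored at 1e-300 so the signed map stays finite.
    """
    c = np.asarray(contrast, float)
    if c.shape[0] != fit.betas.shape[0]:
        raise ValueError("contrast length must match the number of betas")
    if fit.df <= 0:
        raise ValueError("zero residual degrees of freedom")
    x = fit.design.matrix
    cxx = c @ np.linalg.pinv(x.T @ x) @ c
    eff = c @ fit.betas
    se = np.sqrt(np.maximum(fit.sigma2 * cxx, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, eff / se, 0.0)
    p = 2 * stats.t.sf(np.abs(t), fit.df)
    signed = np.sign(eff) * (-np.log10(np.maximum(p, 1e-300)))
    out = ContrastMap(beta=eff, t=t, p=p, signed_logp=signed, name=name)
    if fit.grid_shape is not None:
        out = out.reshape(fit.grid_shape)
    return out
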