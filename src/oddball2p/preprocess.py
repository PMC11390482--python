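"""Raw fluorescence to z-scored dF/F.

The chain is: rigid registration by phase correlation against a batch-
average reference, large-motion frame flagging, ROI trace extraction,
robust neuropil decontamination, baseline (F0) estimation from a two-
component Gaussian mixture over the trace's value distribution, and
per-cell z-scoring of dF/F against session mean and SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.registration import phase_cross_correlation
from sklearn.mixture import GaussianMixture


class DegenerateInputError(ValueError):
    """Raised when an input carries no usable signal (e.g. blank frames)."""


# ---------------------------------------------------------------------------
# Registration


@dataclass
class RegistrationResult:
    displacements: np.ndarray  # (n_frames, 2) integer (dy, dx), px
    discarded_frames: np.ndarray = field(default_factory=lambda: np.array([], int))


def _reference_image(frames: np.ndarray, batch_size: int = 40, n_batches: int = 30) -> np.ndarray:
    """Average of evenly spaced frame batches (30 x 40 where available)."""
    n = frames.shape[0]
    if n < batch_size * n_batches:
        return frames.mean(axis=0)
    starts = np.linspace(0, n - batch_size, n_batches).astype(int)
    picks = np.concatenate([np.arange(s, s + batch_size) for s in starts])
    return frames[picks].mean(axis=0)


def register_frames(frames: np.ndarray) -> RegistrationResult:
    """Integer-pixel rigid displacements of each frame by phase correlation.

    The displacement is the translation of the frame relative to the
    reference: a frame equal to the reference rolled by (dy, dx) yields
    displacement (dy, dx).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (n_frames, h, w) stack with at least 2 frames")
    if np.any(np.ptp(frames, axis=(1, 2)) == 0):
        raise DegenerateInputError("stack contains constant (blank) frames")
    ref = _reference_image(frames)
    disp = np.zeros((frames.shape[0], 2), dtype=int)
    for i, frame in enumerate(frames):
        shift, _, _ = phase_cross_correlation(
            ref, frame, upsample_factor=1, normalization="phase"
        )
        # phase_cross_correlation returns the shift registering the frame
        # onto the reference; the frame's own displacement is its negative
        disp[i] = -shift.astype(int)
    return RegistrationResult(displacements=disp)


def flag_large_motion(
    reg: RegistrationResult, threshold_px: float | None = None
) -> np.ndarray:
    """Indices of frames whose displacement magnitude exceeds threshold.

    With ``threshold_px=None`` the automatic rule flags frames beyond
    10 px or beyond mean + 3 SD of the session's displacement magnitudes.
    """
    mag = np.hypot(*reg.displacements.T)
    if threshold_px is None:
        threshold_px = min(10.0, mag.mean() + 3.0 * mag.std()) if mag.std() > 0 else 10.0
        flagged = np.flatnonzero((mag > 10.0) | (mag > mag.mean() + 3.0 * mag.std()))
    else:
        flagged = np.flatnonzero(mag > threshold_px)
    reg.discarded_frames = flagged
    return flagged


def extract_roi_trace(frames: np.ndarray, roi_mask: np.ndarray) -> np.ndarray:
    """Unweighted mean over mask pixels, per frame."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != frames.shape[1:]:
        raise ValueError("mask shape must match frame shape")
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    return frames[:, roi_mask].mean(axis=1)


# ---------------------------------------------------------------------------
# Neuropil decontamination


def subtract_neuropil(
    cell_trace: np.ndarray,
    neuropil_trace: np.ndarray,
    nu: float = 5.0,
    asymmetry: float = 3.0,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """Estimate the neuropil contamination fraction and remove it.

    The residual model is an asymmetric Student-t: residuals of
    ``cell - r * neuropil - offset`` follow a t distribution with ``nu``
    degrees of freedom whose scale is inflated by ``asymmetry`` for
    positive residuals, so calcium transients (positive excursions absent
    from the neuropil) are down-weighted rather than fitted. The fit is
    iteratively reweighted least squares with an EM scale update,
    alternating (r, offset) and scale. r is clipped to [0, 1).

    Returns (corrected_trace, r_hat) with corrected = cell - r_hat * neuropil.
    """
    y = np.asarray(cell_trace, dtype=float)
    x = np.asarray(neuropil_trace, dtype=float)
    if y.shape != x.shape:
        raise ValueError("cell and neuropil traces must have equal length")
    if y.size < 100:
        raise ValueError("need at least 100 frames to fit the neuropil model")
    if np.ptp(x) == 0 or x.std() < 1e-12:
        warnings.warn("constant neuropil trace: contamination unidentifiable, r=0")
        return y.copy(), 0.0

    # OLS initialization
    xc = x - x.mean()
    r = float(np.dot(xc, y - y.mean()) / np.dot(xc, xc))
    r = float(np.clip(r, 0.0, 1.0 - 1e-6))
    b = float(np.median(y - r * x))
    e = y - r * x - b
    s = max(1.4826 * np.median(np.abs(e - np.median(e))), 1e-9)

    for _ in range(max_iter):
        e = y - r * x - b
        a = np.where(e > 0, asymmetry, 1.0)
        z = e / (s * a)
        u = (nu + 1.0) / (nu + z**2)  # t EM weights
        w = u / (a**2)
        # weighted LS for (r, b)
        sw = w.sum()
        xm = np.dot(w, x) / sw
        ym = np.dot(w, y) / sw
        denom = np.dot(w, (x - xm) ** 2)
        r_new = float(np.dot(w, (x - xm) * (y - ym)) / denom) if denom > 0 else 0.0
        r_new = float(np.clip(r_new, 0.0, 1.0 - 1e-6))
        b_new = ym - r_new * xm
        e = y - r_new * x - b_new
        a = np.where(e > 0, asymmetry, 1.0)
        z = e / (s * a)
        u = (nu + 1.0) / (nu + z**2)
        s_new = float(np.sqrt(np.mean(u * (e / a) ** 2)))
        s_new = max(s_new, 1e-9)
        converged = abs(r_new - r) < tol and abs(s_new - s) < tol * max(s, 1.0)
        r, b, s = r_new, b_new, s_new
        if converged:
            break

    return y - r * x, r


def subtract_neuropil_ols(cell_trace: np.ndarray, neuropil_trace: np.ndarray):
    """Ordinary least-squares contamination estimate (comparison baseline)."""
    y = np.asarray(cell_trace, dtype=float)
    x = np.asarray(neuropil_trace, dtype=float)
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        return y.copy(), 0.0
    r = float(np.clip(np.dot(xc, y - y.mean()) / denom, 0.0, 1.0 - 1e-6))
    return y - r * x, r


# ---------------------------------------------------------------------------
# Baseline and dF/F


def estimate_f0_gmm(trace: np.ndarray, max_iter: int = 50, tol: float = 1e-6) -> float:
    """Baseline fluorescence from a two-component Gaussian mixture.

    The mixture is fitted to the sample distribution of trace values and
    F0 is the mean of the lower component. Initialization is deterministic
    (means at the 25th/90th percentiles), so repeated fits agree exactly.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 200:
        raise ValueError("need at least 200 frames to estimate F0")
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    if np.ptp(trace) == 0:
        return float(trace[0])
    x = trace.reshape(-1, 1)
    q25, q90 = np.percentile(trace, [25, 90])
    var = trace.var()
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        max_iter=max_iter,
        tol=tol,
        n_init=1,
        weights_init=np.array([0.5, 0.5]),
        means_init=np.array([[q25], [q90]]),
        precisions_init=np.array([[[1.0 / var]], [[1.0 / var]]]),
        random_state=0,
    )
    with warnings.catch_warnings():
        # the iteration cap is deliberate; a non-converged fit is still a
        # valid baseline estimate
        warnings.simplefilter("ignore")
        gm.fit(x)
    return float(gm.means_.min())


@dataclass
class DffEntry:
    """One cell's dF/F record."""

    f0: float
    dff: np.ndarray
    z_dff: np.ndarray
    session_mean: float
    session_sd: float
    valid: bool = True
    neuropil_coefficient_hat: float = np.nan


def compute_dff_z(trace: np.ndarray, f0: float) -> DffEntry:
    """dF/F and its session z-score for one cell.

    dff = (trace - F0) / F0; z = (dff - mean) / sd over the session. A
    zero-variance trace cannot be z-scored: the entry is flagged invalid
    (z is returned as zeros) and must be excluded downstream.
    """
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    trace = np.asarray(trace, dtype=float)
    dff = (trace - f0) / f0
    mu = dff.mean()
    sd = dff.std()
    if sd == 0:
        return DffEntry(f0, dff, np.zeros_like(dff), mu, 0.0, valid=False)
    return DffEntry(f0, dff, (dff - mu) / sd, mu, sd)


@dataclass
class DffTraceSet:
    """Per-cell dF/F, z-scored dF/F and fit metadata for a session."""

    f0: np.ndarray  # (n_cells,)
    dff: np.ndarray  # (n_cells, n_frames)
    z_dff: np.ndarray  # (n_cells, n_frames)
    session_mean: np.ndarray
    session_sd: np.ndarray
    neuropil_coefficient_hat: np.ndarray
    valid: np.ndarray  # (n_cells,) bool
    timestamps: np.ndarray | None = None


def preprocess_traces(
    raw: np.ndarray,
    neuropil: np.ndarray,
    timestamps: np.ndarray | None = None,
    f0_on_raw: bool = False,
) -> DffTraceSet:
    """Full trace chain for a set of cells.

    Default order subtracts neuropil first and fits F0 on the
    decontaminated trace; ``f0_on_raw=True`` fits F0 on the raw
    (contaminated) trace instead, matching a literal reading of the
    published order of operations.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    neuropil = np.atleast_2d(np.asarray(neuropil, dtype=float))
    n_cells = raw.shape[0]
    f0 = np.empty(n_cells)
    r_hat = np.empty(n_cells)
    dff = np.empty_like(raw)
    z = np.empty_like(raw)
    mu = np.empty(n_cells)
    sd = np.empty(n_cells)
    valid = np.ones(n_cells, dtype=bool)
    for i in range(n_cells):
        corrected, r = subtract_neuropil(raw[i], neuropil[i])
        source = raw[i] if f0_on_raw else corrected
        f0_i = estimate_f0_gmm(source)
        if f0_i <= 0:
            # pathological baseline; fall back to a low percentile
            f0_i = max(np.percentile(source, 10), 1e-6)
        entry = compute_dff_z(corrected, f0_i)
        f0[i], r_hat[i] = f0_i, r
        dff[i], z[i] = entry.dff, entry.z_dff
        mu[i], sd[i] = entry.session_mean, entry.session_sd
        valid[i] = entry.valid
    return DffTraceSet(
        f0=f0,
        dff=dff,
        z_dff=z,
        session_mean=mu,
        session_sd=sd,
        neuropil_coefficient_hat=r_hat,
        valid=valid,
        timestamps=timestamps,
    )
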