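"""Event-aligned response extraction and cell classification.

A response is the mean z-scored dF/F in a window 0.4-2.0 s after stimulus
onset, baseline-subtracted by the mean over the 0.5 s before onset. On top
of that sit the classification rules: stimulus responsiveness (mean
response above a threshold), prediction-error responsiveness (t-test plus
minimum difference between unexpected block-1 and expected late-block-2
presentations), selectivity and its class cutoffs, the pooled-SD
selectivity index used for noisy bouton traces, and the optogenetic
"recruited" rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig, SessionConfig

__all__ = [
    "build_response_table",
    "classify_cells",
    "classify_pe_responsive",
    "classify_recruited",
    "classify_selectivity_class",
    "classify_stimulus_responsive",
    "compute_response",
    "compute_selectivity",
    "compute_si",
    "late_block2_trial_ids",
    "select_classification_trials",
]


# ---------------------------------------------------------------------------
# Response extraction


# Tolerance (s) for window-edge comparisons: stimulus onsets routinely
# fall exactly on frame times, and raw floating-point comparison would
# assign the boundary frame inconsistently across trials.
TIME_EPS = 1e-6


def _window_mean(trace, timestamps, lo, hi, keep=None):
    """Mean of trace over frames with lo <= t < hi; None if empty."""
    mask = (timestamps >= lo - TIME_EPS) & (timestamps < hi - TIME_EPS)
    total = int(mask.sum())
    if keep is not None:
        mask &= keep
    used = int(mask.sum())
    if used == 0:
        return None, total, 0
    return float(trace[mask].mean()), total, used


def compute_response(
    z_dff: np.ndarray,
    timestamps: np.ndarray,
    onset: float,
    window: tuple[float, float] = (0.4, 2.0),
    baseline: tuple[float, float] = (-0.5, 0.0),
) -> float:
    """Baseline-subtracted window mean for a single event.

    Windows are half-open ([onset+w0, onset+w1) and [onset+b0, onset+b1)),
    so a frame is never counted in both. Raises if either window contains
    no frames.
    """
    resp, _, n_r = _window_mean(z_dff, timestamps, onset + window[0], onset + window[1])
    base, _, n_b = _window_mean(z_dff, timestamps, onset + baseline[0], onset + baseline[1])
    if n_r == 0 or n_b == 0:
        raise ValueError(f"no frames in response or baseline window at onset {onset}")
    return resp - base


def build_response_table(
    z_dff: np.ndarray,
    timestamps: np.ndarray,
    events: pd.DataFrame,
    discarded_frames=None,
    config: AnalysisConfig | None = None,
    cell_valid=None,
) -> pd.DataFrame:
    """Per (cell, event) baseline-subtracted responses.

    Events whose response window loses more than half of its frames to
    motion-flagged (discarded) frames are dropped; otherwise flagged frames
    are simply excluded from the window means. Cells flagged invalid
    (zero-variance dF/F) are omitted.

    Columns: cell_id plus the event columns (trial_id, block, position,
    identity, expectation, is_deviant, led_state, exposure_index, onset)
    and response, baseline (z-scored dF/F units).
    """
    config = config or AnalysisConfig()
    z_dff = np.atleast_2d(z_dff)
    n_cells, n_frames = z_dff.shape
    keep = np.ones(n_frames, dtype=bool)
    if discarded_frames is not None and len(discarded_frames):
        keep[np.asarray(discarded_frames, int)] = False
    w0, w1 = config.response_window
    b0, b1 = config.baseline_window

    onsets = events.onset.to_numpy()
    resp_mask = (timestamps[None, :] >= (onsets + w0 - TIME_EPS)[:, None]) & (
        timestamps[None, :] < (onsets + w1 - TIME_EPS)[:, None]
    )
    base_mask = (timestamps[None, :] >= (onsets + b0 - TIME_EPS)[:, None]) & (
        timestamps[None, :] < (onsets + b1 - TIME_EPS)[:, None]
    )
    total = resp_mask.sum(axis=1)
    resp_mask &= keep[None, :]
    base_mask &= keep[None, :]
    used = resp_mask.sum(axis=1)
    n_base = base_mask.sum(axis=1)
    ok = (
        (total > 0)
        & (n_base > 0)
        & (used >= (1.0 - config.max_discarded_window_fraction) * total)
    )

    rm = resp_mask[ok].astype(float)
    bm = base_mask[ok].astype(float)
    resp = (z_dff @ rm.T) / rm.sum(axis=1)  # (cells, kept events)
    base = (z_dff @ bm.T) / bm.sum(axis=1)

    kept = events.loc[ok].reset_index(drop=True)
    cells = np.arange(n_cells)
    if cell_valid is not None:
        cells = cells[np.asarray(cell_valid, bool)]
    frames = []
    for c in cells:
        df = kept.copy()
        df.insert(0, "cell_id", c)
        df["baseline"] = base[c]
        df["response"] = resp[c] - base[c]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Classification rules


def classify_stimulus_responsive(mean_response: float, threshold: float = 0.5) -> bool:
    """Strictly greater-than threshold on the mean response."""
    return bool(mean_response > threshold)


def classify_pe_responsive(
    unexpected_responses,
    expected_responses,
    alpha: float = 0.05,
    min_diff: float = 0.5,
    equal_var: bool = True,
):
    """Prediction-error responsiveness: t-test AND minimum difference.

    Unexpected responses come from block-1 oddball presentations, expected
    ones from the second half of block 2. Returns (flag, p, diff).
    """
    a = np.asarray(unexpected_responses, float)
    b = np.asarray(expected_responses, float)
    if a.size < 2 or b.size < 2:
        return False, np.nan, np.nan
    diff = a.mean() - b.mean()
    if a.std() == 0 and b.std() == 0:
        if diff == 0:
            return False, 1.0, 0.0
        p = 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    return bool(p < alpha and diff > min_diff), p, float(diff)


def compute_selectivity(r_target: float, r_reference: float) -> float:
    """(R_target - R_reference) / (R_target + R_reference), clipped to [-1, 1].

    Undefined (NaN) when the denominator is zero; such cells are excluded
    from selectivity analyses.
    """
    denom = r_target + r_reference
    if denom == 0:
        return math.nan
    return float(np.clip((r_target - r_reference) / denom, -1.0, 1.0))


def classify_selectivity_class(
    selectivity: float,
    responsive: bool,
    low: float = 0.6,
    high: float = 0.8,
) -> str:
    """non-selective (< low), highly-selective (> high), else intermediate."""
    if not responsive or not np.isfinite(selectivity):
        return "unresponsive"
    if selectivity < low:
        return "non-selective"
    if selectivity > high:
        return "highly-selective"
    return "intermediate"


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    return math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))


def compute_si(responses_a, responses_b) -> float:
    """Selectivity index: mean difference over pooled SD (n-1 weights)."""
    a = np.asarray(responses_a, float)
    b = np.asarray(responses_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 responses per condition")
    sd = _pooled_sd(a, b)
    diff = a.mean() - b.mean()
    if sd == 0:
        return 0.0 if diff == 0 else math.copysign(math.inf, diff)
    return float(diff / sd)


def classify_recruited(
    condition_pairs,
    alpha: float = 0.016,
    min_diff: float = 0.3,
    equal_var: bool = True,
) -> bool:
    """Optogenetic recruitment: significant LED on-vs-off difference.

    ``condition_pairs`` is an iterable of (responses_led_on,
    responses_led_off) per stimulus condition; the cell is recruited if,
    for at least one condition, the two-sided t-test p is below alpha AND
    the on-minus-off difference exceeds min_diff.
    """
    for on, off in condition_pairs:
        on = np.asarray(on, float)
        off = np.asarray(off, float)
        if on.size < 2 or off.size < 2:
            continue
        diff = on.mean() - off.mean()
        if on.std() == 0 and off.std() == 0:
            if diff == 0:
                continue
            p = 0.0
        else:
            p = float(stats.ttest_ind(on, off, equal_var=equal_var).pvalue)
        if p < alpha and diff > min_diff:
            return True
    return False


def select_classification_trials(events: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Event subset used for classification under a figure variant.

    all: every event; led_pooled: every event (LED on and off pooled, the
    selection-bias-avoiding variant); led_off_only: LED-off events only.
    """
    if mode in ("all", "led_pooled"):
        return events
    if mode == "led_off_only":
        return events[events.led_state != "on"]
    raise ValueError(f"unknown classification mode {mode!r}")


# ---------------------------------------------------------------------------
# Session-level classification


def late_block2_trial_ids(session: SessionConfig, fraction: float = 0.5) -> np.ndarray:
    """Trial ids of the last floor(fraction * n_block2) block-2 trials."""
    n_late = int(session.n_trials_block2 * fraction)
    start = session.n_trials_block1 + session.n_trials_block2 - n_late
    return np.arange(start, session.n_trials)


@dataclass
class CellSummary:
    cell_id: int
    responsive_unexpected: bool
    responsive_expected: bool
    stimulus_responsive: bool
    pe_responsive: bool
    pe_p: float
    pe_diff: float
    r_target: float
    r_reference: float
    selectivity: float
    si: float
    selectivity_class: str


def classify_cells(
    response_table: pd.DataFrame,
    session: SessionConfig,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Apply every classification rule per cell.

    Target responses are oddball-identity presentations at the oddball
    position: unexpected ones from block 1, expected ones from late block
    2. The selectivity reference is the mean late-block-2 response to the
    base gratings at the non-oddball mid-corridor positions (A3 or B2 in
    the standard corridor).
    """
    config = config or AnalysisConfig()
    rt = select_classification_trials(response_table, config.classification_mode)
    late_ids = late_block2_trial_ids(session, config.late_block2_fraction)

    at_odd = (rt.position == session.oddball_position) & (
        rt.identity == session.oddball_identity
    )
    unexp = at_odd & (rt.block == 1) & (rt.expectation == "unexpected")
    exp_late = at_odd & rt.trial_id.isin(late_ids)

    ref_positions = [
        p
        for p in range(2, session.n_positions + 1)
        if p != session.oddball_position
    ] or [p for p in range(1, session.n_positions + 1) if p != session.oddball_position]
    ref = (
        rt.position.isin(ref_positions)
        & ~rt.is_deviant
        & rt.trial_id.isin(late_ids)
    )

    rows = []
    for cell_id, grp in rt.groupby("cell_id"):
        idx = grp.index
        u = grp.loc[unexp.loc[idx], "response"].to_numpy()
        e = grp.loc[exp_late.loc[idx], "response"].to_numpy()
        r = grp.loc[ref.loc[idx], "response"].to_numpy()

        resp_u = classify_stimulus_responsive(u.mean(), config.responsive_threshold) if u.size else False
        resp_e = classify_stimulus_responsive(e.mean(), config.responsive_threshold) if e.size else False
        stim_resp = resp_u or resp_e

        pe_flag, pe_p, pe_diff = classify_pe_responsive(
            u, e, config.pe_alpha, config.pe_min_diff, config.equal_var_ttest
        )
        r_t = e.mean() if e.size else math.nan
        r_r = r.mean() if r.size else math.nan
        sel = compute_selectivity(r_t, r_r) if np.isfinite(r_t) and np.isfinite(r_r) else math.nan
        si = compute_si(e, r) if e.size >= 2 and r.size >= 2 else math.nan
        sel_class = classify_selectivity_class(
            sel, resp_e, config.selectivity_low, config.selectivity_high
        )
        rows.append(
            CellSummary(
                cell_id=int(cell_id),
                responsive_unexpected=resp_u,
                responsive_expected=resp_e,
                stimulus_responsive=stim_resp,
                pe_responsive=pe_flag,
                pe_p=pe_p,
                pe_diff=pe_diff,
                r_target=r_t,
                r_reference=r_r,
                selectivity=sel,
                si=si,
                selectivity_class=sel_class,
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
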