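"""Response windows, classification rules, and their recovery properties."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oddball2p.config import SessionConfig
from oddball2p.responses import (
    build_response_table,
    classify_cells,
    classify_pe_responsive,
    classify_recruited,
    classify_selectivity_class,
    classify_stimulus_responsive,
    compute_response,
    compute_selectivity,
    compute_si,
    late_block2_trial_ids,
    select_classification_trials,
)
from oddball2p.synthetic import calcium_kernel


RATE = 7.5


def _timestamps(n=200):
    return np.arange(n) / RATE


def test_response_step_and_constant_traces():
    t = _timestamps()
    onset = 10.0
    z = np.where(t >= onset, 1.0, 0.0)
    assert compute_response(z, t, onset) == pytest.approx(1.0)
    assert compute_response(np.full_like(t, 3.2), t, onset) == pytest.approx(0.0)


def test_response_matches_kernel_window_mean():
    """A planted kernel response equals the window mean of the kernel
    computed directly from the double-exponential formula."""
    t = _timestamps(300)
    onset = t[75]
    dt = 1.0 / RATE
    rel = t - onset
    rise, decay = 0.05, 0.6
    k = np.where(rel >= 0, np.exp(-rel / decay) - np.exp(-rel / rise), 0.0)
    k /= (np.exp(-np.arange(0, 3.6, dt) / decay) - np.exp(-np.arange(0, 3.6, dt) / rise)).max()
    expected = k[(rel >= 0.4) & (rel < 2.0)].mean()
    assert compute_response(k, t, onset) == pytest.approx(expected, abs=1e-12)
    # and agrees with the library kernel used by the generator
    lib = calcium_kernel(RATE, rise, decay)
    assert np.allclose(k[75 : 75 + lib.size], lib, atol=1e-12)


def test_window_frame_counts_at_7p5_hz():
    t = _timestamps(400)
    for onset in t[30:300:37]:
        n_resp = np.sum((t >= onset + 0.4) & (t < onset + 2.0))
        n_base = np.sum((t >= onset - 0.5) & (t < onset))
        assert n_resp == 12
        assert n_base in (3, 4)


def test_response_requires_frames_in_window():
    t = _timestamps(20)
    with pytest.raises(ValueError):
        compute_response(np.zeros(20), t, onset=100.0)


@pytest.mark.parametrize(
    "mean, threshold, expected",
    [
        (0.51, 0.5, True),
        (0.5, 0.5, False),  # strict inequality at the boundary
        (0.15, 0.1, True),  # bouton-mode threshold
        (0.15, 0.2, False),  # raw dF/F threshold variant
    ],
)
def test_stimulus_responsive_thresholds(mean, threshold, expected):
    assert classify_stimulus_responsive(mean, threshold) is expected


def test_pe_responsive_needs_both_significance_and_difference(rng):
    same = rng.normal(0, 1, 20)
    assert classify_pe_responsive(same, same)[0] is False
    # highly significant but small difference: rejected by the 0.5 z rule
    a = rng.normal(0.4, 0.01, 50)
    b = rng.normal(0.0, 0.01, 50)
    flag, p, diff = classify_pe_responsive(a, b, min_diff=0.5)
    assert p < 0.001 and diff < 0.5 and flag is False
    assert classify_pe_responsive(a, b, min_diff=0.3)[0] is True


def test_pe_responsive_power_on_planted_difference():
    """diff = 1.0, n = 16 vs 20, sd = 0.5: detected in >= 95% of draws."""
    rng = np.random.default_rng(7)
    hits = sum(
        classify_pe_responsive(rng.normal(1, 0.5, 16), rng.normal(0, 0.5, 20))[0]
        for _ in range(300)
    )
    assert hits / 300 >= 0.95


@pytest.mark.parametrize(
    "rt, rr, expected",
    [(0.8, 0.8, 0.0), (0.5, 0.0, 1.0), (0.5, -0.1, 1.0), (0.0, 0.5, -1.0)],
)
def test_selectivity_values_and_clipping(rt, rr, expected):
    assert compute_selectivity(rt, rr) == pytest.approx(expected)


def test_selectivity_undefined_for_zero_denominator():
    assert np.isnan(compute_selectivity(0.3, -0.3))


def test_selectivity_antisymmetric_before_clipping(rng):
    for _ in range(50):
        a, b = rng.uniform(0.05, 2, 2)
        raw = (a - b) / (a + b)
        assert raw == pytest.approx(-((b - a) / (b + a)))
        assert compute_selectivity(a, b) == pytest.approx(-compute_selectivity(b, a))


@pytest.mark.parametrize(
    "sel, responsive, expected",
    [
        (0.85, True, "highly-selective"),
        (0.59, True, "non-selective"),
        (0.7, True, "intermediate"),
        (0.6, True, "intermediate"),
        (0.8, True, "intermediate"),
        (0.9, False, "unresponsive"),
    ],
)
def test_selectivity_class_cutoffs(sel, responsive, expected):
    assert classify_selectivity_class(sel, responsive) == expected


def test_si_formula_against_brute_force(rng):
    a = rng.normal(1, 0.7, 13)
    b = rng.normal(0, 1.2, 9)
    pooled = np.sqrt(((13 - 1) * np.var(a, ddof=1) + (9 - 1) * np.var(b, ddof=1)) / 20)
    assert compute_si(a, b) == pytest.approx((a.mean() - b.mean()) / pooled, abs=1e-12)
    assert compute_si([1.0, 1.0, 2.0], [1.0, 1.0, 2.0]) == 0.0
    x = rng.normal(0, 1, 30)
    assert compute_si(x + 1, x) == pytest.approx(1.0 / x.std(ddof=1), rel=1e-9)


def test_recruited_rule(rng):
    same = rng.normal(0, 0.1, 12)
    assert classify_recruited([(same, same)]) is False
    on = rng.normal(0.8, 0.1, 12)
    off = rng.normal(0.0, 0.1, 12)
    assert classify_recruited([(same, same), (on, off)]) is True
    # significant at 0.03 only: rejected under alpha = 0.016
    a = np.array([0.9, 1.4, 0.3, 1.8, 0.2, 1.1])
    b = a - 0.9
    p = stats.ttest_ind(a, b).pvalue
    assert 0.016 < p < 0.05
    assert classify_recruited([(a, b)]) is False
    assert classify_recruited([(a, b)], alpha=0.05) is True


def test_select_classification_trials_modes():
    ev = pd.DataFrame({"led_state": ["on", "off", "none", "on"], "x": range(4)})
    assert len(select_classification_trials(ev, "led_pooled")) == 4
    assert list(select_classification_trials(ev, "led_off_only").x) == [1, 2]
    no_led = pd.DataFrame({"led_state": ["none"] * 3, "x": range(3)})
    assert select_classification_trials(no_led, "all").equals(no_led)
    with pytest.raises(ValueError):
        select_classification_trials(ev, "bogus")


def test_late_block2_is_second_half():
    cfg = SessionConfig(n_animals=1, cells_per_animal=1)
    ids = late_block2_trial_ids(cfg)
    assert ids[0] == 180 and ids[-1] == 199 and len(ids) == 20


def test_response_table_drops_motion_heavy_events(small_session):
    cfg, trials, events, truth, behavior, traces = small_session
    z = np.zeros((1, len(traces.timestamps)))
    full = build_response_table(z, traces.timestamps, events)
    # discard every frame of the first trial's windows
    t0 = events.onset.iloc[0]
    bad = np.flatnonzero((traces.timestamps >= t0) & (traces.timestamps < t0 + 2.5))
    dropped = build_response_table(z, traces.timestamps, events, discarded_frames=bad)
    assert len(dropped) < len(full)
    lost = set(map(tuple, full[["trial_id", "position"]].values)) - set(
        map(tuple, dropped[["trial_id", "position"]].values)
    )
    assert all(t == 0 for t, _ in lost) and len(lost) >= 1


def test_classification_recovers_planted_structure(small_session):
    """Cells with planted amplification are called PE-responsive; cells
    without are not; measured selectivity tracks the planted one."""
    from oddball2p.preprocess import preprocess_traces

    cfg, trials, events, truth, behavior, traces = small_session
    dff = preprocess_traces(traces.raw, traces.neuropil, traces.timestamps)
    rt = build_response_table(dff.z_dff, traces.timestamps, events, cell_valid=dff.valid)
    cls = classify_cells(rt, cfg).set_index("cell_id")
    amplified = truth.pe_gain > 0
    called = cls.pe_responsive.reindex(range(truth.n_cells)).fillna(False).to_numpy()
    assert called[amplified].mean() >= 0.8
    assert called[~amplified].mean() <= 0.1
    sel_ok = cls.selectivity.notna() & (cls.r_target > 0.5)
    got = cls.loc[sel_ok, "selectivity"]
    want = truth.selectivity_true[got.index]
    assert np.corrcoef(got, want)[0, 1] > 0.8


def test_exposure_decay_recoverable_by_regression():
    """Regressing unexpected-response means on exposure index recovers the
    planted per-exposure decay within 0.1."""
    from oddball2p.config import GeneratorConfig
    from oddball2p.preprocess import preprocess_traces
    from oddball2p.synthetic import generate_session

    cfg = SessionConfig(n_animals=2, cells_per_animal=15, seed=21)
    gen = GeneratorConfig(amplitude_jitter=0.05, exposure_decay=0.9)
    trials, events, truth, behavior, traces = generate_session(cfg, gen)
    dff = preprocess_traces(traces.raw, traces.neuropil, traces.timestamps)
    rt = build_response_table(dff.z_dff, traces.timestamps, events, cell_valid=dff.valid)

    amp_cells = np.flatnonzero(truth.pe_gain > 0)
    sub = rt[rt.cell_id.isin(amp_cells) & (rt.expectation == "unexpected")]
    late = rt[
        rt.cell_id.isin(amp_cells)
        & (rt.position == 4)
        & (rt.identity == "C")
        & rt.trial_id.isin(late_block2_trial_ids(cfg))
    ]
    base = late.groupby("cell_id").response.mean()
    # per-cell ratio response_k / baseline - 1 = pe_gain * decay^k
    ratios = (
        sub.set_index("cell_id")
        .assign(rel=lambda d: d.response / base.reindex(d.index) - 1.0)
        .groupby("exposure_index")
        .rel.mean()
    )
    ratios = ratios[ratios > 0]
    slope = np.polyfit(ratios.index, np.log(ratios), 1)[0]
    assert abs(np.exp(slope) - 0.9) < 0.1
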