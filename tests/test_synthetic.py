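"""Trial structure, event flattening and the trace forward model."""

import numpy as np
import pandas as pd
import pytest

from oddball2p.config import ConfigError, GeneratorConfig, SessionConfig
from oddball2p.synthetic import (
    GroundTruth,
    calcium_kernel,
    generate_behavior,
    generate_events,
    generate_frame_stack,
    generate_traces,
    generate_trial_sequence,
    simulate_nested_paired,
)

STD = dict(n_animals=1, cells_per_animal=1)


def _noiseless_truth(
    n_cells=1,
    tuning_C=0.3,
    tuning_base=0.0,
    pe_gain=1.0,
    decay=0.8,
):
    from oddball2p.config import STIMULUS_LABELS

    tuning = np.zeros((n_cells, len(STIMULUS_LABELS)))
    tuning[:, STIMULUS_LABELS.index("C")] = tuning_C
    tuning[:, STIMULUS_LABELS.index("A")] = tuning_base
    tuning[:, STIMULUS_LABELS.index("B")] = tuning_base
    return GroundTruth(
        animal_id=np.zeros(n_cells, int),
        tuning=tuning,
        pe_gain=np.full(n_cells, pe_gain),
        exposure_decay=np.full(n_cells, decay),
        neuropil_coefficient=np.zeros(n_cells),
        f0_true=np.full(n_cells, 100.0),
        noise_sd=np.zeros(n_cells),
        running_gain=np.zeros(n_cells),
        animal_effect=np.zeros(1),
        selectivity_true=np.ones(n_cells),
        cell_class_true=np.array(["highly_selective"] * n_cells, object),
    )


def _noiseless_session(cfg, truth):
    gen = GeneratorConfig(amplitude_jitter=0.0, noise_sd=0.0)
    rng = np.random.default_rng(cfg.seed)
    trials = generate_trial_sequence(cfg, rng)
    events = generate_events(trials, cfg)
    behavior = generate_behavior(cfg, gen, rng, events)
    traces = generate_traces(truth, events, behavior, cfg, gen, rng)
    return trials, events, behavior, traces


@pytest.mark.parametrize(
    "n1, n2, p, expect_odd1",
    [
        (160, 40, 0.10, 16),  # standard session
        (60, 40, 0.15, 9),  # shortened block 1 (axon imaging variant)
        (100, 0, 0.07, 7),
        (10, 5, 0.0, 0),
    ],
)
def test_block1_oddball_count_is_exact(n1, n2, p, expect_odd1):
    cfg = SessionConfig(
        n_trials_block1=n1, n_trials_block2=n2, oddball_probability=p, seed=3, **STD
    )
    tr = generate_trial_sequence(cfg)
    assert len(tr) == n1 + n2
    assert tr[(tr.block == 1) & tr.is_oddball].shape[0] == expect_odd1
    # block 2 is all-oddball: the oddball identity at the oddball position
    b2 = tr[tr.block == 2]
    assert b2.is_oddball.all()
    assert (b2[f"stim_pos{cfg.oddball_position}"] == cfg.oddball_identity).all()
    # block-1 trials precede block-2 trials
    assert tr.block.is_monotonic_increasing


@pytest.mark.parametrize("seed", range(8))
def test_oddball_count_exact_for_every_seed(seed):
    cfg = SessionConfig(seed=seed, **STD)
    tr = generate_trial_sequence(cfg)
    assert tr[(tr.block == 1) & tr.is_oddball].shape[0] == round(0.10 * 160)


def test_trial_table_deterministic_given_seed():
    a = generate_trial_sequence(SessionConfig(seed=42, **STD))
    b = generate_trial_sequence(SessionConfig(seed=42, **STD))
    pd.testing.assert_frame_equal(a, b)


def test_invalid_oddball_position_rejected():
    with pytest.raises(ConfigError):
        SessionConfig(oddball_position=5, **STD)


def test_events_four_per_trial_and_expectation_labels():
    cfg = SessionConfig(seed=0, **STD)
    tr = generate_trial_sequence(cfg)
    ev = generate_events(tr, cfg)
    assert len(ev) == 4 * len(tr)
    # onsets strictly increasing within each trial
    assert ev.groupby("trial_id").onset.apply(lambda s: s.is_monotonic_increasing).all()
    # unexpected only in block 1 at the oddball position
    unexp = ev[ev.expectation == "unexpected"]
    assert (unexp.block == 1).all()
    assert (unexp.position == cfg.oddball_position).all()
    assert len(unexp) == 16
    # block-2 oddball presentations are labelled expected (late-block-2
    # selection happens downstream)
    b2 = ev[(ev.block == 2) & (ev.position == cfg.oddball_position)]
    assert (b2.identity == "C").all()
    assert (b2.expectation == "expected").all()


def test_omission_oddballs_are_unexpected_events():
    cfg = SessionConfig(oddball_identity="omission", seed=5, **STD)
    ev = generate_events(generate_trial_sequence(cfg), cfg)
    unexp = ev[ev.expectation == "unexpected"]
    assert (unexp.identity == "omission").all()
    assert len(unexp) == 16


def test_exposure_index_counts_deviant_presentations():
    cfg = SessionConfig(seed=1, **STD)
    ev = generate_events(generate_trial_sequence(cfg), cfg)
    dev = ev[ev.is_deviant].sort_values("onset")
    assert list(dev.exposure_index) == list(range(len(dev)))


def test_forward_model_no_amplification_when_pe_gain_zero():
    cfg = SessionConfig(n_trials_block1=40, n_trials_block2=10, seed=2, **STD)
    truth = _noiseless_truth(pe_gain=0.0)
    trials, events, behavior, traces = _noiseless_session(cfg, truth)
    dff = traces.raw[0] / truth.f0_true[0] - 1.0
    # amplitude at each oddball onset frame is identical in both blocks
    odd = events[(events.position == 4) & (events.identity == "C")]
    fi = np.searchsorted(behavior.timestamps, odd.onset.to_numpy()) + 1
    amps = dff[fi]
    assert np.allclose(amps, amps[0], atol=1e-9)


def test_forward_model_flat_trace_when_untuned():
    cfg = SessionConfig(n_trials_block1=20, n_trials_block2=5, seed=2, **STD)
    truth = _noiseless_truth(tuning_C=0.0, pe_gain=0.0)
    _, _, _, traces = _noiseless_session(cfg, truth)
    assert np.allclose(traces.raw[0], truth.f0_true[0], atol=1e-9)


def test_forward_model_amplification_follows_exposure_decay():
    """Deconvolving a noiseless trace recovers 1 + decay**k amplification.

    The oracle solves the exact linear system dff = K @ amplitudes (least
    squares on the convolution design matrix), independent of the
    generator's own convolution path.
    """
    cfg = SessionConfig(n_trials_block1=40, n_trials_block2=20, seed=6, **STD)
    decay = 0.8
    truth = _noiseless_truth(pe_gain=1.0, decay=decay)
    trials, events, behavior, traces = _noiseless_session(cfg, truth)
    dff = traces.raw[0] / truth.f0_true[0] - 1.0

    kernel = calcium_kernel(cfg.imaging_rate)
    onset_frames = np.searchsorted(behavior.timestamps, events.onset.to_numpy())
    n = dff.size
    design = np.zeros((n, len(events)))
    for j, f0 in enumerate(onset_frames):
        m = min(len(kernel), n - f0)
        design[f0 : f0 + m, j] = kernel[:m]
    amps, *_ = np.linalg.lstsq(design, dff, rcond=None)

    odd = events.index[(events.position == 4) & (events.identity == "C")]
    base = truth.tuning_for("C")[0]
    for j in odd:
        k = events.loc[j, "exposure_index"]
        expected = base * (1 + decay**k) if events.loc[j, "expectation"] == "unexpected" else base
        assert amps[j] == pytest.approx(expected, abs=1e-6)


def test_event_window_mean_increases_with_planted_amplitude():
    """Monotone affine response of the window mean to the planted amplitude."""
    cfg = SessionConfig(n_trials_block1=20, n_trials_block2=5, seed=9, **STD)
    grid = [0.05, 0.1, 0.2, 0.4, 0.8]
    means = []
    for amp in grid:
        truth = _noiseless_truth(tuning_C=amp, pe_gain=0.0)
        _, events, behavior, traces = _noiseless_session(cfg, truth)
        dff = traces.raw[0] / truth.f0_true[0] - 1.0
        odd = events[(events.position == 4) & (events.identity == "C")]
        onset = odd.onset.iloc[0]
        m = (behavior.timestamps >= onset + 0.4) & (behavior.timestamps < onset + 2.0)
        means.append(dff[m].mean())
    ratios = np.diff(means) / np.diff(grid)
    assert np.all(np.diff(means) > 0)
    assert np.allclose(ratios, ratios[0], rtol=1e-6)  # affine in amplitude


def test_frame_stack_bookkeeping_and_reproducibility():
    zero = generate_frame_stack(n_frames=6, shifts=np.zeros((6, 2), int), seed=1)
    assert np.allclose(zero.frames, zero.frames[0], atol=0.2)  # equal up to noise
    shifts = np.zeros((8, 2), int)
    shifts[5] = (3, -2)
    st = generate_frame_stack(n_frames=8, shifts=shifts, seed=2)
    assert tuple(st.shifts[5]) == (3, -2)
    again = generate_frame_stack(n_frames=8, shifts=shifts, seed=2)
    assert np.array_equal(st.frames, again.frames)
    with pytest.raises(ValueError):
        generate_frame_stack(n_frames=3, shifts=[(40, 0), (0, 0), (0, 0)], seed=0)


def test_nested_paired_has_planted_icc_and_null_differences(rng):
    ids, a, b = simulate_nested_paired(40, 50, icc=0.2, effect=0.0, rng=rng)
    d = a - b
    assert abs(d.mean()) < 0.05
    # animal-level variance of the values matches the planted ICC
    import pandas as pd

    df = pd.DataFrame({"id": ids, "a": a})
    between = df.groupby("id").a.mean().var(ddof=1)
    assert 0.1 < between < 0.3  # icc 0.2 plus sampling noise


def test_behavior_running_nonnegative_and_deceleration_dip():
    cfg = SessionConfig(n_trials_block1=40, n_trials_block2=10, seed=4, **STD)
    gen = GeneratorConfig(oddball_deceleration=8.0)
    rng = np.random.default_rng(0)
    trials = generate_trial_sequence(cfg, rng)
    events = generate_events(trials, cfg)
    beh = generate_behavior(cfg, gen, rng, events)
    assert (beh.running_speed >= 0).all()
    # speed around unexpected onsets is depressed relative to session mean
    unexp = events[events.expectation == "unexpected"]
    fi = np.searchsorted(beh.timestamps, unexp.onset.to_numpy() + 0.5)
    assert beh.running_speed[fi].mean() < beh.running_speed.mean()
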