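"""Synthetic virtual-corridor sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
block of familiar corridor traversals with rare oddball stimuli at one
position, followed by an all-oddball block; calcium transients from tuned
responses; prediction-error amplification restricted to stimulus-selective
cells and decaying with repeated exposure; neuropil contamination; animal-
level random effects; running-speed modulation; and additive noise.

Trial and event tables are plain pandas DataFrames (column dictionaries in
the docstrings); trace-level objects are small dataclasses of arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .config import ConfigError, GeneratorConfig, SessionConfig, STIMULUS_LABELS

__all__ = [
    "BehaviorTrace",
    "FrameStack",
    "GroundTruth",
    "RawTraceSet",
    "calcium_kernel",
    "generate_behavior",
    "generate_events",
    "generate_frame_stack",
    "generate_session",
    "generate_traces",
    "generate_trial_sequence",
    "sample_ground_truth",
    "simulate_nested_paired",
]


# ---------------------------------------------------------------------------
# Trial and event structure


def generate_trial_sequence(config: SessionConfig, rng=None) -> pd.DataFrame:
    """Build the trial table of one oddball session.

    Block 1 contains exactly ``round(p * n)`` oddball trials chosen
    uniformly at random without replacement; in block 2 every trial carries
    the oddball identity at the oddball position.

    Columns: trial_id, block, stim_pos1..stim_posN, is_oddball, led_state,
    trial_start (s).
    """
    rng = np.random.default_rng(config.seed if rng is None else None) if rng is None else rng
    n1, n2 = config.n_trials_block1, config.n_trials_block2
    n_total = n1 + n2
    n_odd = int(round(config.oddball_probability * n1))
    odd_trials = np.sort(rng.choice(n1, size=n_odd, replace=False))

    is_oddball = np.zeros(n_total, dtype=bool)
    is_oddball[odd_trials] = True
    is_oddball[n1:] = True

    stim = np.tile(np.array(config.base_sequence, dtype=object), (n_total, 1))
    stim[is_oddball, config.oddball_position - 1] = config.oddball_identity

    if config.led_fraction > 0:
        led_on = rng.random(n_total) < config.led_fraction
        led_state = np.where(led_on, "on", "off").astype(object)
    else:
        led_state = np.full(n_total, "none", dtype=object)

    table = pd.DataFrame(
        {
            "trial_id": np.arange(n_total),
            "block": np.where(np.arange(n_total) < n1, 1, 2),
            "is_oddball": is_oddball,
            "led_state": led_state,
            "trial_start": np.arange(n_total) * config.trial_duration,
        }
    )
    for p in range(config.n_positions):
        table[f"stim_pos{p + 1}"] = stim[:, p]
    return table


def generate_events(trials: pd.DataFrame, config: SessionConfig) -> pd.DataFrame:
    """Flatten a trial table into one row per stimulus presentation.

    ``expectation`` is "unexpected" for block-1 presentations whose identity
    differs from the trained base sequence at that position; block-2
    presentations are labelled "expected" (the analysis restricts expected
    oddball-identity responses to late block 2 downstream).

    ``exposure_index`` counts prior presentations: for deviant events, prior
    deviant presentations of the same identity anywhere in the corridor;
    for base-sequence events, prior presentations of that identity at that
    position. The counter never resets.

    Columns: trial_id, block, position, identity, onset, duration,
    expectation, is_deviant, led_state, exposure_index.
    """
    rows = []
    deviant_count: dict[str, int] = {}
    base_count: dict[tuple[int, str], int] = {}
    base = list(config.base_sequence)
    for trial in trials.itertuples(index=False):
        for p in range(config.n_positions):
            identity = getattr(trial, f"stim_pos{p + 1}")
            onset = trial.trial_start + config.stimulus_onsets[p]
            deviant = identity != base[p]
            unexpected = deviant and trial.block == 1
            if deviant:
                k = deviant_count.get(identity, 0)
                deviant_count[identity] = k + 1
            else:
                key = (p, identity)
                k = base_count.get(key, 0)
                base_count[key] = k + 1
            rows.append(
                (
                    trial.trial_id,
                    trial.block,
                    p + 1,
                    identity,
                    onset,
                    config.stimulus_duration,
                    "unexpected" if unexpected else "expected",
                    deviant,
                    trial.led_state,
                    k,
                )
            )
    events = pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "block",
            "position",
            "identity",
            "onset",
            "duration",
            "expectation",
            "is_deviant",
            "led_state",
            "exposure_index",
        ],
    )
    return events


# ---------------------------------------------------------------------------
# Ground truth and behavior


@dataclass
class GroundTruth:
    """Generator parameters per cell, kept for recovery tests.

    ``tuning`` is (n_cells, len(STIMULUS_LABELS)) peak fractional dF/F per
    stimulus label; ``selectivity_true`` is the planted
    (target − reference) / (target + reference) selectivity computed from
    tuning amplitudes; ``pe_gain`` is nonzero only for cells whose planted
    selectivity exceeds the generator's amplification threshold.
    """

    animal_id: np.ndarray  # (n_cells,) int
    tuning: np.ndarray  # (n_cells, n_labels) peak dF/F
    tuning_labels: tuple = STIMULUS_LABELS
    pe_gain: np.ndarray = None  # (n_cells,)
    exposure_decay: np.ndarray = None  # (n_cells,)
    neuropil_coefficient: np.ndarray = None  # (n_cells,) in [0, 1)
    f0_true: np.ndarray = None  # (n_cells,) a.u.
    noise_sd: np.ndarray = None  # (n_cells,) a.u.
    running_gain: np.ndarray = None  # (n_cells,) dF/F per (cm/s)
    animal_effect: np.ndarray = None  # (n_animals,) additive dF/F offset
    selectivity_true: np.ndarray = None  # (n_cells,)
    cell_class_true: np.ndarray = None  # (n_cells,) object

    @property
    def n_cells(self) -> int:
        return len(self.animal_id)

    def tuning_for(self, identity: str) -> np.ndarray:
        return self.tuning[:, self.tuning_labels.index(identity)]


@dataclass
class BehaviorTrace:
    """Frame-aligned running speed and pupil area (with planted outliers)."""

    timestamps: np.ndarray  # (n_frames,) s
    running_speed: np.ndarray  # (n_frames,) cm/s, >= 0
    pupil_area: np.ndarray  # (n_frames,) a.u.
    pupil_outlier_idx: np.ndarray = field(default_factory=lambda: np.array([], int))


@dataclass
class RawTraceSet:
    """Per-cell raw fluorescence with matched neuropil traces.

    ``raw`` is the measured (neuropil-contaminated) fluorescence;
    ``cell_fluorescence`` keeps the uncontaminated cell trace as a
    ground-truth auxiliary for recovery tests.
    """

    raw: np.ndarray  # (n_cells, n_frames) a.u.
    neuropil: np.ndarray  # (n_cells, n_frames) a.u.
    timestamps: np.ndarray  # (n_frames,) s
    animal_id: np.ndarray  # (n_cells,)
    session_id: str = "synthetic"
    cell_fluorescence: np.ndarray | None = None


@dataclass
class FrameStack:
    """Small movie with planted per-frame integer shifts (test fixture)."""

    frames: np.ndarray  # (n_frames, h, w)
    shifts: np.ndarray  # (n_frames, 2) planted (dy, dx), px


def sample_ground_truth(
    config: SessionConfig, gen: GeneratorConfig | None = None, rng=None
) -> GroundTruth:
    """Draw per-cell tuning, amplification, contamination and noise."""
    gen = gen or GeneratorConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_cells = config.n_animals * config.cells_per_animal
    animal_id = np.repeat(np.arange(config.n_animals), config.cells_per_animal)

    classes = rng.choice(
        ["highly_selective", "intermediate", "nonselective", "unresponsive"],
        size=n_cells,
        p=[
            gen.frac_highly_selective,
            gen.frac_intermediate,
            gen.frac_nonselective,
            1.0
            - gen.frac_highly_selective
            - gen.frac_intermediate
            - gen.frac_nonselective,
        ],
    )

    target = config.oddball_identity
    base_labels = sorted(set(config.base_sequence))
    tuning = np.zeros((n_cells, len(STIMULUS_LABELS)))
    amp_target = np.zeros(n_cells)
    amp_ref = np.zeros(n_cells)

    hs = classes == "highly_selective"
    im = classes == "intermediate"
    ns = classes == "nonselective"
    un = classes == "unresponsive"

    amp_target[hs] = rng.uniform(*gen.amp_selective, hs.sum())
    sel = rng.uniform(0.85, 0.98, hs.sum())
    amp_ref[hs] = amp_target[hs] * (1 - sel) / (1 + sel)

    amp_target[im] = rng.uniform(*gen.amp_selective, im.sum())
    sel = rng.uniform(0.65, 0.78, im.sum())
    amp_ref[im] = amp_target[im] * (1 - sel) / (1 + sel)

    amp_target[ns] = rng.uniform(*gen.amp_nonselective, ns.sum())
    sel = rng.uniform(-0.2, 0.4, ns.sum())
    amp_ref[ns] = amp_target[ns] * (1 - sel) / (1 + sel)

    amp_target[un] = rng.uniform(0, gen.amp_unresponsive, un.sum())
    amp_ref[un] = rng.uniform(0, gen.amp_unresponsive, un.sum())

    tuning[:, STIMULUS_LABELS.index(target)] = amp_target
    for lab in base_labels:
        tuning[:, STIMULUS_LABELS.index(lab)] = amp_ref

    with np.errstate(invalid="ignore"):
        denom = amp_target + amp_ref
        selectivity_true = np.where(denom > 0, (amp_target - amp_ref) / denom, 0.0)

    # amplification is restricted to stimulus-selective cells; selectivity
    # is only meaningful for cells that respond at all, so the plant is
    # gated on a minimum target amplitude (ratios of near-zero tunings are
    # noise, not selectivity)
    pe_gain = np.where(
        (selectivity_true > gen.pe_selectivity_threshold)
        & (amp_target >= gen.min_responsive_amp),
        gen.pe_gain,
        0.0,
    )

    return GroundTruth(
        animal_id=animal_id,
        tuning=tuning,
        pe_gain=pe_gain,
        exposure_decay=np.full(n_cells, gen.exposure_decay),
        neuropil_coefficient=rng.uniform(*gen.neuropil_coeff_range, n_cells),
        f0_true=np.maximum(rng.normal(gen.f0_mean, gen.f0_sd, n_cells), 20.0),
        noise_sd=np.full(n_cells, gen.noise_sd),
        running_gain=rng.normal(0.0, gen.running_gain_sd, n_cells),
        animal_effect=rng.normal(0.0, gen.animal_effect_sd, config.n_animals),
        selectivity_true=selectivity_true,
        cell_class_true=classes.astype(object),
    )


def _smoothed_noise(n: int, tau_frames: float, rng) -> np.ndarray:
    """Unit-variance Gaussian noise smoothed on a tau-frame scale."""
    x = ndimage.gaussian_filter1d(rng.standard_normal(n), tau_frames, mode="reflect")
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_behavior(
    config: SessionConfig,
    gen: GeneratorConfig | None = None,
    rng=None,
    events: pd.DataFrame | None = None,
) -> BehaviorTrace:
    """Simulate running speed and pupil area on the imaging frame grid.

    Running speed is smoothed positive noise; if the generator's
    ``oddball_deceleration`` is nonzero and events are given, a transient
    speed dip follows each unexpected stimulus onset (to exercise the
    behavioral confound controls). Pupil area carries planted outlier
    spikes for the outlier-filter tests.
    """
    gen = gen or GeneratorConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_frames = int(round(config.n_trials * config.trial_duration * config.imaging_rate))
    t = np.arange(n_frames) / config.imaging_rate

    speed = gen.running_mean + gen.running_sd * _smoothed_noise(
        n_frames, gen.running_tau * config.imaging_rate, rng
    )
    if gen.oddball_deceleration > 0 and events is not None:
        dip_len = int(round(2.0 * config.imaging_rate))
        dip = gen.oddball_deceleration * np.hanning(2 * dip_len)[:dip_len]
        for onset in events.loc[events.expectation == "unexpected", "onset"]:
            i0 = int(np.searchsorted(t, onset))
            i1 = min(i0 + dip_len, n_frames)
            speed[i0:i1] -= dip[: i1 - i0]
    speed = np.maximum(speed, 0.0)

    pupil = 50.0 + 8.0 * _smoothed_noise(n_frames, 10 * config.imaging_rate, rng)
    pupil += rng.normal(0, 0.8, n_frames)
    n_out = int(round(gen.pupil_outlier_fraction * n_frames))
    out_idx = rng.choice(n_frames, size=n_out, replace=False) if n_out else np.array([], int)
    pupil[out_idx] += rng.choice([-1, 1], n_out) * rng.uniform(40, 80, n_out)

    return BehaviorTrace(
        timestamps=t,
        running_speed=speed,
        pupil_area=pupil,
        pupil_outlier_idx=np.sort(out_idx),
    )


# ---------------------------------------------------------------------------
# Trace forward model


def calcium_kernel(imaging_rate: float, rise: float = 0.05, decay: float = 0.6) -> np.ndarray:
    """Double-exponential calcium impulse response, peak-normalized to 1."""
    dt = 1.0 / imaging_rate
    t = np.arange(0.0, 6.0 * decay, dt)
    k = np.exp(-t / decay) - np.exp(-t / rise)
    peak = k.max()
    if peak <= 0:  # decay <= rise degenerate case
        k = np.exp(-t / decay)
        peak = k.max()
    return k / peak


def event_amplitudes(
    truth: GroundTruth,
    events: pd.DataFrame,
    behavior: BehaviorTrace,
    gen: GeneratorConfig,
    rng=None,
) -> np.ndarray:
    """Per (cell, event) response amplitude in fractional dF/F units.

    amplitude = tuning(identity) * (1 + pe_gain * 1{unexpected} * decay**k)
                * (1 + jitter)  +  running_gain * speed(onset)  +  animal_effect

    where k is the event's exposure index. Omission events carry the
    stimulus term only (zero unless the cell is tuned to omission): they
    add no running/animal drive because nothing is displayed.
    """
    n_cells = truth.n_cells
    ident_idx = np.array(
        [truth.tuning_labels.index(i) for i in events.identity], dtype=int
    )
    tuning = truth.tuning[:, ident_idx]  # (cells, events)
    unexpected = (events.expectation == "unexpected").to_numpy()
    k = events.exposure_index.to_numpy()
    pe_factor = 1.0 + truth.pe_gain[:, None] * unexpected[None, :] * (
        truth.exposure_decay[:, None] ** k[None, :]
    )
    amp = tuning * pe_factor
    if gen.amplitude_jitter > 0 and rng is not None:
        amp = amp * np.maximum(
            1.0 + gen.amplitude_jitter * rng.standard_normal(amp.shape), 0.0
        )
    speed_at = np.interp(events.onset.to_numpy(), behavior.timestamps, behavior.running_speed)
    extras = (
        truth.running_gain[:, None] * speed_at[None, :]
        + truth.animal_effect[truth.animal_id][:, None]
    )
    omission = (events.identity == "omission").to_numpy()
    amp = amp + extras * (~omission)[None, :]
    return amp


def generate_traces(
    truth: GroundTruth,
    events: pd.DataFrame,
    behavior: BehaviorTrace,
    config: SessionConfig,
    gen: GeneratorConfig | None = None,
    rng=None,
) -> RawTraceSet:
    """Render raw fluorescence traces from ground truth.

    trace = f0_true * (1 + signal) + noise, where signal is the amplitude
    impulse train convolved with the calcium kernel; the measured trace is
    additionally contaminated as raw = trace + r_np * neuropil.
    """
    gen = gen or GeneratorConfig()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if np.any(truth.f0_true <= 0):
        raise ConfigError("f0_true must be positive for every cell")

    n_frames = len(behavior.timestamps)
    n_cells = truth.n_cells
    amp = event_amplitudes(truth, events, behavior, gen, rng)

    # small tolerance so onsets that coincide with a frame time land on
    # that frame regardless of floating-point rounding of onset * rate
    frame_idx = np.searchsorted(behavior.timestamps, events.onset.to_numpy() - 1e-6)
    frame_idx = np.minimum(frame_idx, n_frames - 1)
    # scatter-add amplitudes at onset frames (events can share a frame)
    impulses = np.zeros((n_cells, n_frames))
    np.add.at(impulses.T, frame_idx, amp.T)

    kernel = calcium_kernel(config.imaging_rate, gen.kernel_rise, gen.kernel_decay)
    sig = signal.fftconvolve(impulses, kernel[None, :], mode="full", axes=1)[:, :n_frames]

    cell = truth.f0_true[:, None] * (1.0 + sig)
    cell = cell + rng.normal(0.0, 1.0, cell.shape) * truth.noise_sd[:, None]

    # Per-animal neuropil: slow background fluctuations around a mean,
    # measured per cell with small independent readout noise.
    tau = gen.neuropil_slow_tau * config.imaging_rate
    np_animal = np.stack(
        [
            gen.neuropil_mean + gen.neuropil_slow_sd * _smoothed_noise(n_frames, tau, rng)
            for _ in range(config.n_animals)
        ]
    )
    neuropil = np_animal[truth.animal_id] + rng.normal(0.0, 0.3, (n_cells, n_frames))
    raw = cell + truth.neuropil_coefficient[:, None] * neuropil

    return RawTraceSet(
        raw=raw,
        neuropil=neuropil,
        timestamps=behavior.timestamps.copy(),
        animal_id=truth.animal_id.copy(),
        session_id=f"synthetic-seed{config.seed}",
        cell_fluorescence=cell,
    )


def generate_session(config: SessionConfig, gen: GeneratorConfig | None = None):
    """Generate a complete session: trials, events, truth, behavior, traces.

    Returns (trials, events, truth, behavior, traces); all randomness flows
    from ``config.seed`` through one generator, so identical configurations
    yield identical sessions.
    """
    gen = gen or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    trials = generate_trial_sequence(config, rng)
    events = generate_events(trials, config)
    truth = sample_ground_truth(config, gen, rng)
    behavior = generate_behavior(config, gen, rng, events)
    traces = generate_traces(truth, events, behavior, config, gen, rng)
    return trials, events, truth, behavior, traces


# ---------------------------------------------------------------------------
# Registration fixture


def generate_frame_stack(
    n_frames: int = 20,
    shifts=None,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    noise_sd: float = 0.02,
    max_shift: int = 8,
) -> FrameStack:
    """Textured template translated by planted integer shifts plus noise.

    Shifts wrap around the frame edge (circular translation), keeping the
    planted displacement recoverable exactly by phase correlation. By
    default most frames are still and ~30% carry a shift, emulating
    intermittent motion; pass ``shifts`` to plant a specific pattern.
    """
    rng = np.random.default_rng(seed)
    if shifts is None:
        shifts = np.zeros((n_frames, 2), dtype=int)
        moved = rng.random(n_frames) < 0.3
        shifts[moved] = rng.integers(-max_shift, max_shift + 1, size=(int(moved.sum()), 2))
    shifts = np.asarray(shifts, dtype=int)
    if shifts.shape != (n_frames, 2):
        raise ValueError("shifts must be (n_frames, 2)")
    if np.any(np.abs(shifts) >= min(shape) // 4):
        raise ValueError("planted shifts must stay below frame size / 4")

    template = ndimage.gaussian_filter(rng.random(shape), 1.5)
    template = (template - template.min()) / (template.max() - template.min())
    frames = np.stack(
        [
            np.roll(template, tuple(s), axis=(0, 1)) + rng.normal(0, noise_sd, shape)
            for s in shifts
        ]
    )
    return FrameStack(frames=frames, shifts=shifts)


def generate_contaminated_pair(
    seed: int,
    r_np: float = 0.7,
    n_frames: int = 3000,
    transient_rate: float = 0.05,
    transient_amp: tuple[float, float] = (10.0, 60.0),
    back_contamination: float = 0.0,
    noise_sd: float = 2.0,
    imaging_rate: float = 7.5,
):
    """Cell/neuropil trace pair with a planted contamination coefficient.

    The measured cell trace is ``cell + r_np * slow_background``; the
    measured neuropil trace is the slow background plus, optionally, a
    ``back_contamination`` fraction of the cell's own transients (the
    bleed-through that biases a plain least-squares coefficient upward on
    transient-rich data).

    Returns (measured_cell, measured_neuropil).
    """
    rng = np.random.default_rng(seed)
    k = calcium_kernel(imaging_rate)
    spikes = (rng.random(n_frames) < transient_rate) * rng.uniform(
        *transient_amp, n_frames
    )
    transients = signal.fftconvolve(spikes, k)[:n_frames]
    slow = 30.0 + 8.0 * _smoothed_noise(n_frames, 20 * imaging_rate, rng)
    cell = 100.0 + transients + rng.normal(0, noise_sd, n_frames)
    measured_cell = cell + r_np * slow
    measured_np = slow + back_contamination * transients + rng.normal(0, 0.5, n_frames)
    return measured_cell, measured_np


# ---------------------------------------------------------------------------
# Nested paired data for resampling-test calibration


def simulate_nested_paired(
    n_animals: int,
    cells_per_animal: int,
    icc: float = 0.0,
    effect: float = 0.0,
    rng=None,
):
    """Paired condition values for cells nested in animals.

    Both conditions share an animal random effect (variance = icc) and a
    cell effect, so the intraclass correlation of the values is ``icc``
    while the paired differences are exchangeable under the null —
    mirroring the additive per-animal amplitude offset of the session
    generator. ``effect`` is an additive shift of condition a, in units of
    the total value SD (1).

    Returns (animal_ids, value_a, value_b).
    """
    if not (0.0 <= icc < 1.0):
        raise ValueError("icc must be in [0, 1)")
    rng = np.random.default_rng(rng)
    n = n_animals * cells_per_animal
    animal_ids = np.repeat(np.arange(n_animals), cells_per_animal)
    alpha = rng.normal(0.0, np.sqrt(icc), n_animals)[animal_ids]
    within = (1.0 - icc) / 2.0
    cell = rng.normal(0.0, np.sqrt(within), n)
    a = alpha + cell + rng.normal(0.0, np.sqrt(within), n) + effect
    b = alpha + cell + rng.normal(0.0, np.sqrt(within), n)
    return animal_ids, a, b
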