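"""Configuration objects for synthetic sessions and analysis runs.

Every threshold printed in the study is a named field defaulting to the
published value, so figure-variant analyses are configuration switches
rather than code forks.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import yaml

STIMULUS_LABELS = ("A", "B", "C", "D", "E", "omission")


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SessionConfig:
    """Parameters of one virtual-corridor oddball session.

    The defaults describe the standard session: a 160-trial block in which
    the stimulus at corridor position 4 is replaced by a novel grating C on
    a randomly chosen 10% of trials, followed by a 40-trial block in which
    C appears at position 4 on every trial.
    """

    n_trials_block1: int = 160
    n_trials_block2: int = 40
    oddball_probability: float = 0.10
    oddball_position: int = 4
    oddball_identity: str = "C"
    base_sequence: Sequence[str] = ("A", "B", "A", "B")
    imaging_rate: float = 7.5  # frames / s
    stimulus_duration: float = 2.0  # s
    n_animals: int = 5
    cells_per_animal: int = 40
    seed: int = 0

    # Trial timing (s). Onsets are relative to trial start; desk-scale
    # trials are shorter than real corridor traversals but preserve the
    # response/baseline window geometry.
    trial_duration: float = 12.0
    stimulus_onsets: Sequence[float] = (1.0, 3.6, 6.2, 8.8)

    # LED (optogenetics) bookkeeping. Fraction of trials with LED on;
    # 0 means led_state is "none" for every trial.
    led_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.oddball_probability <= 1.0):
            raise ConfigError("oddball_probability must be in [0, 1]")
        if self.n_trials_block1 < 1 or self.n_trials_block2 < 0:
            raise ConfigError("trial counts must be positive")
        if self.imaging_rate <= 0:
            raise ConfigError("imaging_rate must be > 0")
        n_pos = len(self.base_sequence)
        if not (1 <= self.oddball_position <= n_pos):
            raise ConfigError(
                f"oddball_position must be in 1..{n_pos}, got {self.oddball_position}"
            )
        if self.oddball_identity not in STIMULUS_LABELS:
            raise ConfigError(f"unknown stimulus label {self.oddball_identity!r}")
        if len(self.stimulus_onsets) != n_pos:
            raise ConfigError("stimulus_onsets must match base_sequence length")

    @property
    def n_trials(self) -> int:
        return self.n_trials_block1 + self.n_trials_block2

    @property
    def n_positions(self) -> int:
        return len(self.base_sequence)


@dataclass
class GeneratorConfig:
    """Ground-truth parameter distributions for the trace forward model.

    Amplitudes are fractional fluorescence modulations (peak dF/F of a
    single stimulus response); the mapping to z-scored units is set by the
    cell's own session variability, as in the real pipeline.
    """

    # Cell-class mixture (highly selective / intermediate / non-selective
    # responsive / unresponsive); must sum to 1.
    frac_highly_selective: float = 0.25
    frac_intermediate: float = 0.15
    frac_nonselective: float = 0.30

    amp_selective: tuple[float, float] = (0.25, 0.40)  # tuned peak dF/F
    amp_nonselective: tuple[float, float] = (0.15, 0.30)
    amp_unresponsive: float = 0.02  # residual tuning of "unresponsive" cells

    pe_gain: float = 1.0  # amplification for unexpected events, selective cells
    pe_selectivity_threshold: float = 0.8  # amplification restricted above this
    min_responsive_amp: float = 0.1  # amplification needs a real response to act on
    exposure_decay: float = 0.9  # per-exposure multiplicative decay

    f0_mean: float = 100.0  # a.u.
    f0_sd: float = 15.0
    noise_sd: float = 3.0  # a.u., additive white noise on raw fluorescence
    amplitude_jitter: float = 0.25  # trial-to-trial multiplicative sd

    neuropil_coeff_range: tuple[float, float] = (0.3, 0.8)
    neuropil_mean: float = 30.0  # a.u.
    neuropil_slow_sd: float = 6.0
    neuropil_slow_tau: float = 20.0  # s, smoothing scale of slow background

    animal_effect_sd: float = 0.05  # additive per-animal amplitude offset
    running_gain_sd: float = 0.002  # per-cell gain, dF/F per (cm/s)

    # Calcium kernel (double exponential), s
    kernel_rise: float = 0.05
    kernel_decay: float = 0.6

    # Behavior
    running_mean: float = 12.0  # cm/s
    running_sd: float = 5.0
    running_tau: float = 4.0  # s, smoothing scale
    oddball_deceleration: float = 0.0  # cm/s dip after oddball onset (0=off)
    pupil_outlier_fraction: float = 0.01

    def __post_init__(self) -> None:
        fracs = (
            self.frac_highly_selective
            + self.frac_intermediate
            + self.frac_nonselective
        )
        if fracs > 1.0 + 1e-9:
            raise ConfigError("cell-class fractions exceed 1")
        if not (0.0 < self.exposure_decay <= 1.0):
            raise ConfigError("exposure_decay must be in (0, 1]")
        if self.f0_mean <= 0:
            raise ConfigError("f0_mean must be > 0")


@dataclass
class AnalysisConfig:
    """Every analysis threshold of the study, under its printed default."""

    response_window: tuple[float, float] = (0.4, 2.0)  # s after onset
    baseline_window: tuple[float, float] = (-0.5, 0.0)  # s relative to onset
    responsive_threshold: float = 0.5  # z-scored dF/F
    responsive_threshold_raw: float = 0.2  # raw dF/F variant
    responsive_threshold_bouton: float = 0.1  # bouton variant
    pe_alpha: float = 0.05
    pe_min_diff: float = 0.5  # z-scored dF/F; 0.3 variant selectable
    recruited_alpha: float = 0.016
    recruited_min_diff: float = 0.3
    selectivity_low: float = 0.6
    selectivity_high: float = 0.8
    late_block2_fraction: float = 0.5
    classification_mode: str = "all"  # all | led_pooled | led_off_only
    equal_var_ttest: bool = True
    motion_threshold_px: float = 10.0
    max_discarded_window_fraction: float = 0.5
    f0_on_raw: bool = False  # fit F0 before neuropil subtraction if True
    n_boot: int = 10000

    def __post_init__(self) -> None:
        if self.response_window[0] >= self.response_window[1]:
            raise ConfigError("response_window must be increasing")
        if self.baseline_window[0] >= self.baseline_window[1]:
            raise ConfigError("baseline_window must be increasing")
        for name in ("responsive_threshold", "pe_min_diff", "recruited_min_diff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.classification_mode not in ("all", "led_pooled", "led_off_only"):
            raise ConfigError(f"unknown classification_mode {self.classification_mode!r}")


@dataclass
class RunConfig:
    """Top-level configuration for an end-to-end run."""

    session: SessionConfig = field(default_factory=SessionConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(cfg) -> dict:
    return _to_plain(cfg)


def config_hash(cfg) -> str:
    """Stable SHA-256 digest of a configuration, for provenance records."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _build(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_run_config(path) -> RunConfig:
    """Read a RunConfig from a YAML document (missing keys take defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config document must be a mapping")
    return RunConfig(
        session=_build(SessionConfig, data.get("session", {})),
        generator=_build(GeneratorConfig, data.get("generator", {})),
        analysis=_build(AnalysisConfig, data.get("analysis", {})),
        seed=int(data.get("seed", 0)),
    )


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
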