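"""End-to-end orchestration: simulate, analyze, calibrate.

`run_simulate` writes a complete synthetic session to disk; `run_analyze`
executes preprocessing, response extraction, classification and the
class-wise hierarchical-bootstrap contrast on a session directory and
writes the report tables; `run_calibrate` measures type-I error and power
of the hierarchical bootstrap on simulated nested datasets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .config import (
    AnalysisConfig,
    RunConfig,
    SessionConfig,
    config_hash,
    config_to_dict,
    save_run_config,
)
from .hierstats import bonferroni, bootstrap_ci, cohens_d, hierarchical_bootstrap_test
from .preprocess import preprocess_traces
from .responses import build_response_table, classify_cells, late_block2_trial_ids
from .synthetic import generate_frame_stack, generate_session, simulate_nested_paired

log = logging.getLogger("oddball2p")

SELECTIVITY_CLASSES = ("highly-selective", "intermediate", "non-selective", "unresponsive")


class DataError(RuntimeError):
    """A session directory is missing or malformed."""


def run_simulate(cfg: RunConfig, outdir, force: bool = False, write_stack: bool = False):
    """Generate a synthetic session and write it to ``outdir``."""
    outdir = Path(outdir)
    paths = _io.session_paths(outdir)
    if outdir.exists() and any(p.exists() for p in paths.values()) and not force:
        raise FileExistsError(f"{outdir} already holds a session (use force)")
    outdir.mkdir(parents=True, exist_ok=True)

    trials, events, truth, behavior, traces = generate_session(cfg.session, cfg.generator)
    _io.write_table(trials, paths["trials"])
    _io.write_table(events, paths["events"])
    _io.write_behavior(behavior, paths["behavior"])
    _io.write_session_h5(paths["container"], traces, truth)
    save_run_config(cfg, paths["config"])
    if write_stack:
        stack = generate_frame_stack(n_frames=40, seed=cfg.seed)
        _io.write_stack_tiff(stack, paths["stack"])
        _io.write_shifts(stack, paths["shifts"])
    log.info(
        "simulated session: %d trials, %d cells, %d frames -> %s",
        len(trials),
        traces.raw.shape[0],
        traces.raw.shape[1],
        outdir,
    )
    return outdir


def per_cell_condition_means(
    response_table: pd.DataFrame,
    session: SessionConfig,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Mean unexpected (block 1) and expected (late block 2) oddball-identity
    response per cell: the paired data of the amplification contrast."""
    config = config or AnalysisConfig()
    late_ids = late_block2_trial_ids(session, config.late_block2_fraction)
    at_odd = (response_table.position == session.oddball_position) & (
        response_table.identity == session.oddball_identity
    )
    unexp = response_table[at_odd & (response_table.expectation == "unexpected")]
    exp = response_table[at_odd & response_table.trial_id.isin(late_ids)]
    u = unexp.groupby("cell_id").response.agg(["mean", "size"])
    e = exp.groupby("cell_id").response.agg(["mean", "size"])
    out = u.join(e, lsuffix="_unexpected", rsuffix="_expected", how="inner")
    out.columns = ["mean_unexpected", "n_unexpected", "mean_expected", "n_expected"]
    return out.reset_index()


@dataclass
class ReportBundle:
    classification: pd.DataFrame
    condition_means: pd.DataFrame
    statistics: pd.DataFrame
    provenance: dict


def amplification_by_class(
    pairs: pd.DataFrame,
    classification: pd.DataFrame,
    animal_id: np.ndarray,
    n_boot: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hierarchical-bootstrap contrast (unexpected vs expected) per
    selectivity class, Bonferroni-adjusted across classes."""
    merged = pairs.merge(
        classification[["cell_id", "selectivity_class"]], on="cell_id"
    )
    merged["animal_id"] = animal_id[merged.cell_id.to_numpy()]
    rows = []
    rng = np.random.default_rng(seed)
    for cls in SELECTIVITY_CLASSES:
        grp = merged[merged.selectivity_class == cls]
        n_animals = grp.animal_id.nunique()
        if len(grp) < 4 or n_animals < 2:
            rows.append((cls, len(grp), n_animals, np.nan, np.nan, np.nan, np.nan, np.nan))
            continue
        a = grp.mean_unexpected.to_numpy()
        b = grp.mean_expected.to_numpy()
        res = hierarchical_bootstrap_test(
            grp.animal_id.to_numpy(), a, b, n_boot=n_boot,
            seed=int(rng.integers(2**31)),
        )
        d = cohens_d(a, b).cohens_d
        lo, hi = bootstrap_ci(a - b, n_boot=min(n_boot, 2000), seed=int(rng.integers(2**31)))
        rows.append((cls, len(grp), n_animals, res.observed_stat, res.p_value, d, lo, hi))
    stats_df = pd.DataFrame(
        rows,
        columns=[
            "selectivity_class",
            "n_cells",
            "n_animals",
            "mean_amplification",
            "p_value",
            "cohens_d",
            "ci_low",
            "ci_high",
        ],
    )
    tested = stats_df.p_value.notna()
    stats_df["p_adjusted"] = np.nan
    stats_df.loc[tested, "p_adjusted"] = bonferroni(
        stats_df.loc[tested, "p_value"].to_numpy(), int(tested.sum())
    )
    return stats_df


def run_analyze(session_dir, cfg: RunConfig, outdir=None) -> ReportBundle:
    """Full analysis of a session directory; writes the report tables."""
    session_dir = Path(session_dir)
    paths = _io.session_paths(session_dir)
    for key in ("trials", "events", "container"):
        if not paths[key].exists():
            raise DataError(f"missing session file: {paths[key]}")
    events = _io.read_table(paths["events"])
    traces, truth = _io.read_session_h5(paths["container"])

    log.info("preprocess: %d cells x %d frames", *traces.raw.shape)
    dff = preprocess_traces(
        traces.raw, traces.neuropil, traces.timestamps, f0_on_raw=cfg.analysis.f0_on_raw
    )
    n_invalid = int((~dff.valid).sum())
    if n_invalid:
        log.warning("%d cells flagged invalid (zero-variance dF/F): excluded", n_invalid)

    rt = build_response_table(
        dff.z_dff, traces.timestamps, events, config=cfg.analysis, cell_valid=dff.valid
    )
    classification = classify_cells(rt, cfg.session, cfg.analysis)
    classification["animal_id"] = traces.animal_id[classification.cell_id.to_numpy()]
    classification["neuropil_coefficient_hat"] = dff.neuropil_coefficient_hat[
        classification.cell_id.to_numpy()
    ]
    classification["f0_hat"] = dff.f0[classification.cell_id.to_numpy()]

    pairs = per_cell_condition_means(rt, cfg.session, cfg.analysis)
    stats_df = amplification_by_class(
        pairs, classification, traces.animal_id, n_boot=cfg.analysis.n_boot, seed=cfg.seed
    )

    cond_means = pairs.merge(
        classification[["cell_id", "selectivity_class"]], on="cell_id"
    )
    class_means = (
        cond_means.groupby("selectivity_class")[["mean_unexpected", "mean_expected"]]
        .mean()
        .reset_index()
    )

    provenance = {
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "session_id": traces.session_id,
        "n_cells": int(traces.raw.shape[0]),
        "n_invalid_cells": n_invalid,
        "config": config_to_dict(cfg),
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _io.write_table(classification, outdir / "classification.tsv")
        _io.write_table(class_means, outdir / "condition_means.tsv")
        _io.write_table(stats_df, outdir / "statistics.tsv")
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, default=str)

    return ReportBundle(classification, class_means, stats_df, provenance)


def run_calibrate(
    n_datasets: int = 200,
    n_boot: int = 1000,
    n_animals: int = 5,
    cells_per_animal: int = 40,
    iccs=(0.0, 0.2),
    effects=(0.0, 0.5, 1.0),
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Rejection rate of the hierarchical bootstrap across effect sizes and
    intraclass correlations (type-I error at effect 0, power elsewhere)."""
    rng = np.random.default_rng(seed)
    rows = []
    for icc in iccs:
        for effect in effects:
            rejections = 0
            for _ in range(n_datasets):
                ids, a, b = simulate_nested_paired(
                    n_animals, cells_per_animal, icc=icc, effect=effect, rng=rng
                )
                res = hierarchical_bootstrap_test(
                    ids, a, b, n_boot=n_boot, seed=int(rng.integers(2**31))
                )
                rejections += res.p_value < alpha
            rows.append((icc, effect, rejections / n_datasets, n_datasets, n_boot))
    return pd.DataFrame(
        rows, columns=["icc", "effect", "rejection_rate", "n_datasets", "n_boot"]
    )
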