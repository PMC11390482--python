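#!/usr/bin/env python
"""Generate the default synthetic oddball session.

Writes the full session (trial/event/behavior tables plus the HDF5 trace
container with ground truth) to scratch/session, and a compact summary of
what was planted to results/session_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from oddball2p.config import RunConfig
from oddball2p.io import read_session_h5, read_table, session_paths
from oddball2p.pipeline import run_simulate

ROOT = Path(__file__).resolve().parents[1]
SESSION_DIR = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main():
    cfg = RunConfig()
    cfg.seed = cfg.session.seed = 11
    run_simulate(cfg, SESSION_DIR, force=True)
    paths = session_paths(SESSION_DIR)
    trials = read_table(paths["trials"])
    _, truth = read_session_h5(paths["container"])

    summary = pd.DataFrame(
        {
            "quantity": [
                "n_trials",
                "n_block1_oddballs",
                "n_block2_trials",
                "n_cells",
                "n_amplified_cells",
                "n_highly_selective_true",
                "n_animals",
            ],
            "value": [
                len(trials),
                int(((trials.block == 1) & trials.is_oddball).sum()),
                int((trials.block == 2).sum()),
                truth.n_cells,
                int((truth.pe_gain > 0).sum()),
                int((truth.cell_class_true == "highly_selective").sum()),
                len(set(truth.animal_id)),
            ],
        }
    )
    RESULTS.mkdir(exist_ok=True)
    summary.to_csv(RESULTS / "session_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"\nsession written to {SESSION_DIR}")


if __name__ == "__main__":
    main()
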