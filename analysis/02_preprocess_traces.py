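#!/usr/bin/env python
"""Preprocess the session traces and check parameter recovery.

Runs neuropil decontamination, GMM baseline estimation and z-scored dF/F
on the session from 01, then compares the recovered neuropil coefficients
and baselines against the generator's ground truth. Writes per-cell
recovery numbers to results/preprocess_recovery.tsv.
"""

import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from oddball2p.io import read_session_h5, session_paths
from oddball2p.preprocess import preprocess_traces

ROOT = Path(__file__).resolve().parents[1]
SESSION_DIR = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main():
    if not session_paths(SESSION_DIR)["container"].exists():
        subprocess.run([sys.executable, str(ROOT / "analysis" / "01_simulate_session.py")], check=True)
    traces, truth = read_session_h5(session_paths(SESSION_DIR)["container"])
    dff = preprocess_traces(traces.raw, traces.neuropil, traces.timestamps)

    table = pd.DataFrame(
        {
            "cell_id": np.arange(truth.n_cells),
            "animal_id": truth.animal_id,
            "r_np_true": truth.neuropil_coefficient,
            "r_np_hat": dff.neuropil_coefficient_hat,
            "f0_true": truth.f0_true,
            "f0_hat": dff.f0,
            "valid": dff.valid,
        }
    )
    table["r_np_error"] = table.r_np_hat - table.r_np_true
    table["f0_rel_error"] = (table.f0_hat - table.f0_true) / table.f0_true
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "preprocess_recovery.tsv", sep="\t", index=False, float_format="%.6g")

    print(f"cells: {truth.n_cells} ({int(dff.valid.sum())} valid)")
    print(f"neuropil coefficient |error|: median {table.r_np_error.abs().median():.4f}, "
          f"max {table.r_np_error.abs().max():.4f}")
    print(f"F0 relative |error|: median {table.f0_rel_error.abs().median():.4%}, "
          f"max {table.f0_rel_error.abs().max():.4%}")
    print(f"wrote {RESULTS / 'preprocess_recovery.tsv'}")


if __name__ == "__main__":
    main()
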