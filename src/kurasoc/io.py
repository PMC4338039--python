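"""Tabular export of simulation traces and reports (CSV via pandas)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


def trial_record_frame(record) -> pd.DataFrame:
    """Fully recorded trial traces as a tidy table (one row per sample)."""
    if record.theta is None or record.p is None:
        raise ValueError("record traces missing: run the trial with record='full'")
    n = record.theta.shape[0]
    t = np.arange(n) * record.dt * record.rec_stride
    cols = {"time_s": t}
    for i in range(3):
        cols[f"theta_{i + 1}"] = record.theta[:, i]
        cols[f"p_{i + 1}"] = record.p[:, i]
    cols["x"] = record.pose[:, 0]
    cols["y"] = record.pose[:, 1]
    cols["heading"] = record.pose[:, 2]
    cols["dist_A"] = record.dist[:, 0]
    cols["dist_B"] = record.dist[:, 1]
    return pd.DataFrame(cols)


def dump_trial_record(record, path: str | Path) -> None:
    trial_record_frame(record).to_csv(path, index=False)


def envelope_frame(env) -> pd.DataFrame:
    """Envelope series Phi as a two-column table (time_s, phi)."""
    t = np.arange(env.values.size) / env.fs
    return pd.DataFrame({"time_s": t, "phi": env.values})


def reports_frame(reports) -> pd.DataFrame:
    """One row per condition x estimator summary from FractalReport objects."""
    return pd.DataFrame([r.to_dict() for r in reports])
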