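"""Writers for simulation output: trajectory/scalars CSV, per-species
kymograph CSVs with a JSON sidecar, shape snapshots and run provenance."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulator import SimulationOutput

__all__ = ["write_output", "read_trajectory"]


def write_output(out: SimulationOutput, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    pd.DataFrame({"t": out.t, "x": out.centroid[:, 0],
                  "y": out.centroid[:, 1]}).to_csv(d / "trajectory.csv",
                                                   index=False)
    pd.DataFrame({
        "t": out.t,
        "filgap_c": out.filgap_c,
        "bound_filgap": out.bound_filgap,
        "frac_fast": out.frac_fast,
    }).to_csv(d / "scalars.csv", index=False)

    for name, mat in out.kymographs.items():
        np.savetxt(d / f"kymo_{name}.csv", mat, delimiter=",")
    with open(d / "kymo_meta.json", "w") as fh:
        json.dump({"times": out.kymo_times.tolist(),
                   "species": sorted(out.kymographs)}, fh)

    rows = []
    for t, poly in zip(out.snapshot_times, out.snapshots):
        for x, y in poly:
            rows.append((t, x, y))
    pd.DataFrame(rows, columns=["t", "x", "y"]).to_csv(
        d / "snapshots.csv", index=False)

    with open(d / "provenance.json", "w") as fh:
        json.dump({
            "config": out.config,
            "master_seed": out.master_seed,
            "version": __version__,
            "source_position": (None if out.source_position is None
                                else out.source_position.tolist()),
            "totals_start": out.totals_start,
            "totals_end": out.totals_end,
        }, fh, indent=1)
    return d


def read_trajectory(directory: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(directory) / "trajectory.csv")
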