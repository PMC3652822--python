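"""Count-table and trajectory I/O.

CFU count tables are plain CSV (`time_h,cfu_total,cfu_normal,
cfu_persister,replicate`; the last three optional) with generating
parameters, noise model and schema version in a JSON sidecar
(`<name>.meta.json`) rather than embedded comments.  Trajectories export
as `time_h,n,p,total,phase_label`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .params import ValidationError

__all__ = [
    "CountTable",
    "read_count_table",
    "write_count_table",
    "trajectory_to_csv",
    "trajectory_from_csv",
]

SCHEMA_VERSION = 1
_REQUIRED = ["time_h", "cfu_total"]
_OPTIONAL = ["cfu_normal", "cfu_persister", "replicate"]


@dataclass
class CountTable:
    """CFU counts over time, optionally split by phenotype and replicate.

    ``frame`` columns: ``time_h`` and ``cfu_total`` (required),
    ``cfu_normal``, ``cfu_persister``, ``replicate`` (optional).
    ``metadata`` records how the table was produced (generator
    parameters, noise model, seed, schema version).
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.frame
        for col in _REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"count table missing required column '{col}'")
        for col in [c for c in df.columns if c.startswith("cfu_")]:
            bad = df.index[df[col] < 0]
            if len(bad):
                raise ValidationError(
                    f"negative count in column '{col}' at row {int(bad[0])}"
                )
        groups = df.groupby("replicate") if "replicate" in df.columns else [(0, df)]
        for rep, g in groups:
            t = g["time_h"].to_numpy(float)
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValidationError(
                    f"time_h must be strictly increasing within replicate {rep!r}"
                )
        self.metadata.setdefault("schema_version", SCHEMA_VERSION)

    def replicate(self, rep) -> pd.DataFrame:
        if "replicate" not in self.frame.columns:
            return self.frame
        return self.frame[self.frame["replicate"] == rep].reset_index(drop=True)

    @property
    def n_replicates(self) -> int:
        if "replicate" not in self.frame.columns:
            return 1
        return int(self.frame["replicate"].nunique())


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_count_table(table: CountTable, path) -> None:
    """Write CSV plus its JSON metadata sidecar (UTF-8, '.' decimal)."""
    path = Path(path)
    cols = [c for c in _REQUIRED + _OPTIONAL if c in table.frame.columns]
    table.frame.to_csv(path, index=False, columns=cols, encoding="utf-8")
    with open(_sidecar(path), "w", encoding="utf-8") as fh:
        json.dump(table.metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_count_table(path) -> CountTable:
    """Read a CSV count table (and its sidecar metadata, if present) with
    strict header validation."""
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValidationError(
                f"{path.name}: missing required column '{col}' "
                f"(found: {', '.join(df.columns)})"
            )
    unknown = [c for c in df.columns if c not in _REQUIRED + _OPTIONAL]
    if unknown:
        raise ValidationError(f"{path.name}: unknown column(s) {unknown}")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        with open(sc, encoding="utf-8") as fh:
            meta = json.load(fh)
    return CountTable(frame=df, metadata=meta)


def trajectory_to_csv(traj: Trajectory, path) -> None:
    """Export a trajectory as `time_h,n,p,total,phase_label`."""
    labels = traj.phase_labels if traj.phase_labels else [""] * len(traj)
    df = pd.DataFrame(
        {
            "time_h": traj.times,
            "n": traj.n,
            "p": traj.p,
            "total": traj.total,
            "phase_label": labels,
        }
    )
    df.to_csv(path, index=False, encoding="utf-8")


def trajectory_from_csv(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("time_h", "n", "p", "total", "phase_label"):
        if col not in df.columns:
            raise ValidationError(f"{path.name}: missing required column '{col}'")
    labels = ["" if (isinstance(x, float) and math.isnan(x)) else str(x) for x in df["phase_label"]]
    return Trajectory(
        times=df["time_h"].to_numpy(float),
        n=df["n"].to_numpy(float),
        p=df["p"].to_numpy(float),
        phase_labels=labels,
    )
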