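"""Assay CSV/TSV parsing and writing, run configuration.

The assay format is a delimited text table with header
``dose_Gy,surviving_fraction[,sd]`` (comma or tab separated); lines starting
with ``#`` are comments.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from typing import Optional

import numpy as np

from .exceptions import DataError
from .fitting import SurvivalAssayData

__all__ = ["read_assay_csv", "write_assay_csv", "RunConfig"]

_REQUIRED = ("dose_Gy", "surviving_fraction")


def read_assay_csv(path) -> SurvivalAssayData:
    """Parse an assay table, tolerating TSV and ``#`` comment lines.

    Raises :class:`~umasurv.exceptions.DataError` with the offending line
    number for missing columns, non-numeric cells or negative doses.
    """
    path = os.fspath(path)
    header = None
    idx = {}
    doses, surv, sds = [], [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            delim = "\t" if "\t" in line else ","
            cells = [c.strip() for c in line.split(delim)]
            if header is None:
                header = cells
                missing = [c for c in _REQUIRED if c not in header]
                if missing:
                    raise DataError(
                        f"{path}:{lineno}: missing required column(s) {missing}; "
                        f"got header {header}"
                    )
                idx = {name: header.index(name) for name in header}
                continue
            try:
                dose = float(cells[idx["dose_Gy"]])
                s = float(cells[idx["surviving_fraction"]])
            except (ValueError, IndexError) as exc:
                raise DataError(f"{path}:{lineno}: non-numeric or missing cell ({exc})") from exc
            if dose < 0:
                raise DataError(f"{path}:{lineno}: negative dose {dose}")
            doses.append(dose)
            surv.append(s)
            if "sd" in idx:
                cell = cells[idx["sd"]] if idx["sd"] < len(cells) else ""
                if cell == "":
                    sds.append(math.nan)
                else:
                    try:
                        sds.append(float(cell))
                    except ValueError as exc:
                        raise DataError(f"{path}:{lineno}: non-numeric sd cell {cell!r}") from exc
    if header is None or not doses:
        raise DataError(f"{path}: no data rows found")
    sd_arr = None
    if sds and not all(math.isnan(v) for v in sds):
        sd_arr = np.asarray(sds)
    label = os.path.splitext(os.path.basename(path))[0]
    return SurvivalAssayData(
        doses=np.asarray(doses), survival=np.asarray(surv), sd=sd_arr, label=label
    )


def write_assay_csv(data: SurvivalAssayData, path, precision: int = 10) -> None:
    """Write an assay in the same dialect :func:`read_assay_csv` accepts."""
    with open(os.fspath(path), "w", encoding="utf-8") as fh:
        cols = ["dose_Gy", "surviving_fraction"] + (["sd"] if data.sd is not None else [])
        fh.write(",".join(cols) + "\n")
        for i in range(len(data)):
            row = [f"{data.doses[i]:.{precision}g}", f"{data.survival[i]:.{precision}g}"]
            if data.sd is not None:
                row.append("" if math.isnan(data.sd[i]) else f"{data.sd[i]:.{precision}g}")
            fh.write(",".join(row) + "\n")


@dataclasses.dataclass
class RunConfig:
    """Serialisable run configuration; CLI flags override file values."""

    input: Optional[str] = None
    output: Optional[str] = None
    report: Optional[str] = None
    a_max: float = 100.0
    outlier_threshold: float = 2.5
    tie_tolerance: float = 1e-6
    weighting: str = "delta"
    fractions: int = 5
    dose: float = 10.0
    clonogen_counts: tuple = (1e4, 1e5, 1e6)
    target_fractions: int = 3
    precision: int = 10
    seed: int = 0
    sigma_log: float = 0.05
    replicates: int = 1

    def to_file(self, path) -> None:
        with open(os.fspath(path), "w", encoding="utf-8") as fh:
            d = dataclasses.asdict(self)
            d["clonogen_counts"] = list(self.clonogen_counts)
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(os.fspath(path), "r", encoding="utf-8") as fh:
            d = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        if "clonogen_counts" in d:
            d["clonogen_counts"] = tuple(float(v) for v in d["clonogen_counts"])
        return cls(**d)

    def merged(self, **overrides) -> "RunConfig":
        """Return a copy with the non-None overrides applied."""
        updates = {k: v for k, v in overrides.items() if v is not None}
        return dataclasses.replace(self, **updates)
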