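"""Quantitative time-series datasets and the EXP text dialect.

An EXP file is a whitespace/tab-delimited table whose first header token is
``time`` and whose remaining headers are observable names; rows are numeric
with the literal ``nan`` marking a missing measurement.  In the study-shaped
configuration all quantitative records belong to the WT variant (relative
intensity measurements scaled into (0, 1]).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import pandas as pd

__all__ = ["QuantRecord", "QuantDataset", "read_exp_file", "write_exp_file"]


@dataclass(frozen=True)
class QuantRecord:
    """One measurement: (variant, observable, time) -> value or missing."""

    variant: str
    observable: str
    time: float
    value: Optional[float]  # None = missing ("nan")

    @property
    def missing(self) -> bool:
        return self.value is None or math.isnan(self.value)


@dataclass
class QuantDataset:
    """Collection of quantitative records; missing rows carry no weight."""

    records: List[QuantRecord]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n(self) -> int:
        """Effective (non-missing) record count."""
        return sum(1 for r in self.records if not r.missing)

    def non_missing(self) -> List[QuantRecord]:
        return [r for r in self.records if not r.missing]

    def required_times(self) -> Dict[str, List[float]]:
        req: Dict[str, set] = {}
        for r in self.records:
            if not r.missing:
                req.setdefault(r.variant, set()).add(r.time)
        return {v: sorted(ts) for v, ts in req.items()}

    def to_frame(self) -> pd.DataFrame:
        """Wide table: time rows x observable columns (NaN = missing)."""
        rows: Dict[float, Dict[str, float]] = {}
        obs: List[str] = []
        for r in self.records:
            rows.setdefault(r.time, {})[r.observable] = (
                float("nan") if r.missing else r.value
            )
            if r.observable not in obs:
                obs.append(r.observable)
        frame = pd.DataFrame.from_dict(rows, orient="index").reindex(
            columns=obs
        )
        frame.index.name = "time"
        return frame.sort_index()


def read_exp_file(path, variant: str = "WT") -> QuantDataset:
    """Read an EXP table; every record is attributed to ``variant``."""
    frame = pd.read_csv(path, sep=r"\s+")
    if frame.columns[0] != "time":
        raise ValueError(
            f"{path}: first EXP header token must be 'time', "
            f"got {frame.columns[0]!r}"
        )
    records = []
    for _, row in frame.iterrows():
        t = float(row["time"])
        for obs in frame.columns[1:]:
            v = float(row[obs])
            records.append(
                QuantRecord(variant, obs, t, None if math.isnan(v) else v)
            )
    return QuantDataset(records, provenance=str(path))


def write_exp_file(path, data: QuantDataset) -> None:
    frame = data.to_frame()
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("time\t" + "\t".join(frame.columns) + "\n")
        for t, row in frame.iterrows():
            cells = [
                "nan" if math.isnan(v) else f"{v:.10g}" for v in row.to_numpy()
            ]
            fh.write(f"{t:g}\t" + "\t".join(cells) + "\n")
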