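"""Keyed tables of named scalar/series results with units."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

__all__ = ["AnalysisReport"]


@dataclass
class AnalysisReport:
    """An ordered table of named results.

    Each row is a dict with at least ``name``, ``value`` and ``units``;
    extra keys become extra columns.  Iteration order is insertion order,
    which keeps report files byte-stable across runs.
    """

    name: str = "report"
    rows: list[dict[str, Any]] = field(default_factory=list)

    def add(self, name: str, value: Any, units: str = "", **extra: Any) -> None:
        self.rows.append({"name": name, "value": value, "units": units, **extra})

    def get(self, name: str) -> Any:
        for row in self.rows:
            if row["name"] == name:
                return row["value"]
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(r["name"] == name for r in self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"name": self.name, "rows": self.rows},
                                         indent=2, default=str) + "\n")
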