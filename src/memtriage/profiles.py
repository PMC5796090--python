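"""Per-residue scalar tracks (SASA, conservation, RMSF) keyed by residue number."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

import pandas as pd


@dataclass
class ResidueProfile:
    """A scalar value per residue, indexed by 1-based reference residue number.

    Parameters
    ----------
    values
        Mapping of residue number to scalar value.
    units
        Free-form unit annotation (e.g. ``"A^2"``, ``"dimensionless"``).
    """

    values: Dict[int, float] = field(default_factory=dict)
    units: str = ""

    def __getitem__(self, resnum: int) -> float:
        return self.values[resnum]

    def __setitem__(self, resnum: int, value: float) -> None:
        self.values[resnum] = value

    def __contains__(self, resnum: int) -> bool:
        return resnum in self.values

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self.values))

    def to_series(self) -> pd.Series:
        s = pd.Series(self.values, name="value").sort_index()
        s.index.name = "residue"
        return s

    def to_tsv(self, path) -> None:
        df = self.to_series().reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, units: str = "") -> "ResidueProfile":
        df = pd.read_csv(path, sep="\t")
        res_col, val_col = df.columns[0], df.columns[1]
        values = {int(r): float(v) for r, v in zip(df[res_col], df[val_col])}
        return cls(values=values, units=units)

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float], units: str = "") -> "ResidueProfile":
        return cls(values={int(k): float(v) for k, v in mapping.items()}, units=units)
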