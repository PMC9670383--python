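"""The complement table: gene counts per species x superfamily x group.

A "complement" is the full set of genes a species possesses in a given
detoxification superfamily (CYP, CCE, GST); groups are CYP clans
(Mitochondrial, CYP2, CYP3, CYP4), CCE functional classes (HPP, Dietary,
ND) and GST classes (Delta ... Microsomal).  Superfamily totals and the
grand total are never stored - they are always recomputed as sums, so the
table cannot go inconsistent.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd

SUPERFAMILIES = ("CYP", "CCE", "GST")

#: Canonical group order, matching the comparative table layout.
CANONICAL_GROUPS = {
    "CYP": ("Mitochondrial", "CYP2", "CYP3", "CYP4"),
    "CCE": ("HPP", "Dietary", "ND"),
    "GST": ("Delta", "Epsilon", "Omega", "Sigma", "Theta", "Zeta",
            "Microsomal"),
}


class ComplementTable:
    """Long-format counts with sum-derived totals."""

    COLUMNS = ("species", "superfamily", "group", "count")

    def __init__(self, frame: Optional[pd.DataFrame] = None):
        if frame is None:
            frame = pd.DataFrame(columns=list(self.COLUMNS))
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"complement table missing columns {missing}")
        frame = frame[list(self.COLUMNS)].copy()
        frame["count"] = frame["count"].astype(int)
        if (frame["count"] < 0).any():
            raise ValueError("complement counts must be nonnegative")
        self.frame = frame

    # -- construction ------------------------------------------------------

    @classmethod
    def from_counts(cls, counts: Iterable[Tuple[str, str, str, int]]
                    ) -> "ComplementTable":
        frame = pd.DataFrame(list(counts), columns=list(cls.COLUMNS))
        return cls(frame)

    @classmethod
    def from_labeled_genes(cls, genes: Iterable[Tuple[str, str, str]]
                           ) -> "ComplementTable":
        """Count one row per (species, superfamily, group) gene label."""
        rows = pd.DataFrame(list(genes),
                            columns=["species", "superfamily", "group"])
        if rows.empty:
            return cls()
        counts = (rows.value_counts(["species", "superfamily", "group"])
                  .rename("count").reset_index())
        return cls(counts)

    @classmethod
    def from_tsv(cls, path) -> "ComplementTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    # -- queries -----------------------------------------------------------

    @property
    def species(self) -> Tuple[str, ...]:
        return tuple(dict.fromkeys(self.frame["species"]))

    def get(self, species: str, superfamily: str, group: str) -> int:
        sel = self.frame[(self.frame["species"] == species)
                         & (self.frame["superfamily"] == superfamily)
                         & (self.frame["group"] == group)]
        return int(sel["count"].sum())

    def group_counts(self, species: str, superfamily: str) -> pd.Series:
        sel = self.frame[(self.frame["species"] == species)
                         & (self.frame["superfamily"] == superfamily)]
        return sel.set_index("group")["count"]

    def superfamily_total(self, species: str, superfamily: str) -> int:
        return int(self.group_counts(species, superfamily).sum())

    def grand_total(self, species: str) -> int:
        sel = self.frame[self.frame["species"] == species]
        return int(sel["count"].sum())

    def wide(self) -> pd.DataFrame:
        """Species-by-(superfamily, group) matrix with zero fill."""
        return (self.frame.pivot_table(index="species",
                                       columns=["superfamily", "group"],
                                       values="count", aggfunc="sum",
                                       fill_value=0).astype(int))

    def totals_frame(self) -> pd.DataFrame:
        """Per-species superfamily totals and grand total, sum-derived."""
        rows = []
        for sp in self.species:
            row = {"species": sp}
            for fam in dict.fromkeys(self.frame["superfamily"]):
                row[fam] = self.superfamily_total(sp, fam)
            row["Total"] = self.grand_total(sp)
            rows.append(row)
        return pd.DataFrame(rows).set_index("species")
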