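"""Gene-family expansion statistics.

Expansions are tested with Pearson chi-square on two-by-two contingency
tables built between a pair of species under one of three schemes:

(a) ``vs_genome`` - detoxification genes vs the rest of the genes of the
    genome (needs genome-wide totals);
(b) ``vs_other_superfamilies`` - one superfamily vs the sum of the other two
    superfamilies under study;
(c) ``within_superfamily`` - one clan/class vs the rest of the same
    superfamily.

The chi-square statistic is the plain Pearson sum((O-E)^2/E) on 1 df with
expected counts from the table margins; the Yates continuity correction is
available but off by default.  Expected cells below 5 set a flag rather than
suppressing the test.  Benjamini-Hochberg adjustment is offered for the many
pairwise comparisons these schemes generate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from math import floor, isinf
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from statsmodels.stats.multitest import multipletests

from .complement import SUPERFAMILIES, ComplementTable
from .reconcile import EventMatrix

SCHEME_VS_GENOME = "vs_genome"
SCHEME_VS_OTHER_SUPERFAMILIES = "vs_other_superfamilies"
SCHEME_WITHIN_SUPERFAMILY = "within_superfamily"
SCHEMES = (SCHEME_VS_GENOME, SCHEME_VS_OTHER_SUPERFAMILIES,
           SCHEME_WITHIN_SUPERFAMILY)


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # in-group count, species A
    b: int  # out-group count, species A
    c: int  # in-group count, species B
    d: int  # out-group count, species B
    row_labels: Tuple[str, str] = ("species_a", "species_b")
    col_labels: Tuple[str, str] = ("in_group", "out_group")
    scheme: str = ""

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be nonnegative")
        if self.total == 0:
            raise ValueError("contingency table has zero grand total")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class TestResult:
    chi2: float
    df: int
    p_value: float
    low_expected_flag: bool
    adjusted_p: Optional[float] = None


def build_contingency(scheme: str, species_a: str, species_b: str,
                      complement: ComplementTable,
                      superfamily: Optional[str] = None,
                      group: Optional[str] = None,
                      genome_totals: Optional[Dict[str, int]] = None
                      ) -> ContingencyTable2x2:
    """Construct the 2x2 table for one scheme and species pair.

    ``superfamily`` selects the in-group for schemes (a) and (b); for scheme
    (c) the in-group is ``group`` within ``superfamily`` and the out-group is
    the rest of that superfamily.  For scheme (a), ``superfamily=None``
    uses the whole detoxification complement as the in-group.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one "
                         f"of {SCHEMES}")

    def in_out(species: str) -> Tuple[int, int]:
        if scheme == SCHEME_VS_GENOME:
            if genome_totals is None or species not in genome_totals:
                raise ValueError(
                    f"scheme {scheme!r} requires genome_totals for "
                    f"{species!r}")
            in_count = (complement.grand_total(species) if superfamily is None
                        else complement.superfamily_total(species,
                                                          superfamily))
            out_count = genome_totals[species] - in_count
            if out_count < 0:
                raise ValueError(f"genome total for {species!r} is smaller "
                                 "than its detoxification complement")
            return in_count, out_count
        if scheme == SCHEME_VS_OTHER_SUPERFAMILIES:
            if superfamily is None:
                raise ValueError("scheme requires a superfamily")
            in_count = complement.superfamily_total(species, superfamily)
            out_count = sum(complement.superfamily_total(species, fam)
                            for fam in SUPERFAMILIES if fam != superfamily)
            return in_count, out_count
        # within superfamily
        if superfamily is None or group is None:
            raise ValueError("scheme requires superfamily and group")
        in_count = complement.get(species, superfamily, group)
        out_count = complement.superfamily_total(species,
                                                 superfamily) - in_count
        return in_count, out_count

    a, b = in_out(species_a)
    c, d = in_out(species_b)
    label = group if group is not None else (superfamily or "detox")
    return ContingencyTable2x2(a, b, c, d,
                               row_labels=(species_a, species_b),
                               col_labels=(label, f"rest"),
                               scheme=scheme)


def pearson_chi_square(table: ContingencyTable2x2,
                       yates: bool = False) -> TestResult:
    """Pearson chi-square test of homogeneity on a 2x2 table, 1 df."""
    obs = table.as_array()
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    expected = np.outer(row, col) / total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(((diff ** 2) / expected).sum())
    p = float(_chi2_dist.sf(chi2, df=1))
    return TestResult(chi2=chi2, df=1, p_value=p,
                      low_expected_flag=bool((expected < 5).any()))


def adjust_p(p_values: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment; Benjamini-Hochberg step-up by default."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}.get(
        method, method)
    return multipletests(p, method=key)[1]


def compute_proportion(numerator: float, denominator: float,
                       decimals: int = 1) -> float:
    """Percentage 100*num/den, rounded half-away-from-zero.

    Half-away-from-zero matches how the study prints shares such as
    17/29 -> 58.6% and 14/47 -> 29.8%.
    """
    if denominator == 0:
        raise ZeroDivisionError("proportion with zero denominator")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FoldRatio:
    duplications: int
    losses: int
    raw: float          # duplications / losses (inf when losses == 0)
    truncated: float    # floored to one decimal, the printed style

    @property
    def infinite(self) -> bool:
        return isinf(self.raw)


def fold_ratio(event_matrix: EventMatrix, group: str) -> FoldRatio:
    """Duplications-to-losses ratio for one family group over all branches.

    Reported raw and truncated to one decimal: a group with 154 duplications
    and 54 losses has raw ratio 2.851..., printed as a 2.8-fold expansion.
    Zero losses give an infinite, flagged ratio.
    """
    dups = event_matrix.event_total("Duplications", [group])
    losses = event_matrix.event_total("Losses", [group])
    if losses == 0:
        return FoldRatio(dups, losses, float("inf"), float("inf"))
    raw = dups / losses
    return FoldRatio(dups, losses, raw, floor(raw * 10) / 10)
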