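"""Packaged in-study fixture tables.

Two small tables are shipped with the package: the curated complement
counts per species x superfamily x clan/class, and the per-branch
duplication/loss event matrix from the manual reconciliation of the five
hemipteran species.  Only cells are stored; every total is recomputed as a
sum.  The originally printed totals are kept alongside so that
:func:`fixture_discrepancies` can report where the published totals do not
match their own cells (two do not).
"""

from __future__ import annotations

from importlib import resources
from typing import Dict, List, Union

import pandas as pd

from .complement import ComplementTable
from .reconcile import EventMatrix

#: Branch order of the event-matrix fixture (terminal, internal, outgroup).
TABLE2_BRANCHES = ("Clec", "Rpro", "CR", "Hhal", "Nvir", "HN", "HET", "Nlug")
TABLE2_GROUPS = ("MIT", "CYP2", "CYP3", "CYP4", "GST", "CCE")

#: CYP family groups of the event matrix (the four clans).
CYP_EVENT_GROUPS = ("MIT", "CYP2", "CYP3", "CYP4")


def _data_path(name: str):
    return resources.files("detoxevol.data") / name


def load_study_fixture(table_id: str) -> Union[ComplementTable, EventMatrix]:
    """Load a packaged fixture: ``"table1"`` (complement counts) or
    ``"table2"`` (per-branch event matrix)."""
    if table_id == "table1":
        with resources.as_file(_data_path("table1.tsv")) as path:
            table = ComplementTable.from_tsv(path)
        if table.frame.empty:
            raise ValueError("malformed complement fixture: no rows")
        return table
    if table_id == "table2":
        with resources.as_file(_data_path("table2.tsv")) as path:
            frame = pd.read_csv(path, sep="\t", comment="#")
        required = {"branch", "event", "group", "count"}
        if not required.issubset(frame.columns):
            raise ValueError("malformed event-matrix fixture")
        cells = [(str(r.branch), str(r.event), str(r.group), int(r.count))
                 for r in frame.itertuples(index=False)]
        return EventMatrix.from_cells(cells, branches=TABLE2_BRANCHES,
                                      groups=TABLE2_GROUPS)
    raise ValueError(f"unknown fixture {table_id!r}; "
                     "expected 'table1' or 'table2'")


def load_printed_totals() -> pd.DataFrame:
    with resources.as_file(_data_path("table2_printed_totals.tsv")) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def fixture_discrepancies() -> List[str]:
    """Compare recomputed event-matrix totals with the printed totals.

    Returns one message per mismatch.  The shipped table has two: the
    printed row total of the Nlug duplications row and the printed grand
    total both disagree with the cells they summarise.
    """
    matrix = load_study_fixture("table2")
    printed = load_printed_totals()
    problems: List[str] = []
    for row in printed.itertuples(index=False):
        if row.kind == "branch":
            computed = matrix.branch_total(str(row.branch), str(row.event))
            if computed != row.printed_total:
                problems.append(
                    f"branch {row.branch} {row.event}: cells sum to "
                    f"{computed}, printed total is {row.printed_total}")
        elif row.kind == "group":
            computed = matrix.group_total(str(row.group))
            if computed != row.printed_total:
                problems.append(
                    f"group {row.group}: cells sum to {computed}, printed "
                    f"total is {row.printed_total}")
        elif row.kind == "grand":
            computed = matrix.total_events()
            if computed != row.printed_total:
                problems.append(
                    f"grand total: cells sum to {computed}, printed total "
                    f"is {row.printed_total}")
    return problems
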