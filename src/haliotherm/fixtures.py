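"""Packaged reference tables from the heat-stress study.

``table1`` lists the 35 differentially expressed heat-shock-protein (HSP)
family genes with read counts and log2 fold changes for the sensitive (RL)
and tolerant (YL) lines; ``table2`` lists the 12 down-regulated genes of
the cell-cycle and DNA-replication pathways.  A few duplicated annotation
names in table1 (distinct unigenes sharing a description) carry a (RL)/(YL)
suffix so that gene names are unique; the numeric values are verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["FixtureTable", "load_fixture", "FIXTURES"]

FIXTURES = ("table1", "table2")

_EXPECTED_ROWS = {"table1": 35, "table2": 12}


@dataclass
class FixtureTable:
    """A parsed fixture with a ``membership`` column in
    {both, RL_only, YL_only}."""

    name: str
    frame: pd.DataFrame

    def membership_counts(self) -> dict[str, int]:
        c = self.frame["membership"].value_counts()
        return {k: int(c.get(k, 0)) for k in ("both", "RL_only", "YL_only")}

    def rows(self, membership: str | None = None) -> pd.DataFrame:
        if membership is None:
            return self.frame
        if membership not in ("both", "RL_only", "YL_only"):
            raise ValueError(f"unknown membership: {membership!r}")
        return self.frame[self.frame["membership"] == membership]

    def __len__(self):
        return len(self.frame)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("haliotherm.data") / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _validate_table1(df: pd.DataFrame) -> None:
    rc = df[["readcount_heat_RL", "readcount_control_RL",
             "readcount_heat_YL", "readcount_control_YL"]]
    if (rc.to_numpy(float) < 0).any():
        raise ValueError("table1: negative read count")
    has_rl = df["log2fc_RL"].notna()
    has_yl = df["log2fc_YL"].notna()
    expect = np.select(
        [has_rl & has_yl, has_rl, has_yl],
        ["both", "RL_only", "YL_only"], default="invalid")
    if not (df["membership"].to_numpy() == expect).all():
        raise ValueError("table1: membership inconsistent with present values")


def _validate_table2(df: pd.DataFrame) -> None:
    if df["pathways"].isna().any():
        raise ValueError("table2: missing pathway annotation")
    has_rl = df["log2fc_RL"].notna()
    has_yl = df["log2fc_YL"].notna()
    expect = np.select(
        [has_rl & has_yl, has_rl, has_yl],
        ["both", "RL_only", "YL_only"], default="invalid")
    df["membership"] = expect
    if (expect == "invalid").any():
        raise ValueError("table2: row with no fold change in either line")


def load_fixture(name: str) -> FixtureTable:
    """Load a packaged fixture by name (``table1`` or ``table2``)."""
    if name not in FIXTURES:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    df = _read(name)
    if len(df) != _EXPECTED_ROWS[name]:
        raise ValueError(
            f"{name}: expected {_EXPECTED_ROWS[name]} rows, got {len(df)}")
    if name == "table1":
        _validate_table1(df)
    else:
        _validate_table2(df)
    return FixtureTable(name=name, frame=df)


def table2_pathway_sets(table: FixtureTable) -> pd.Series:
    """Normalized pathway membership per gene (lower-cased set)."""
    return table.frame.set_index("gene_id")["pathways"].map(
        lambda s: {p.strip().lower() for p in str(s).split(",")})
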