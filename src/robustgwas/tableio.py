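"""TSV input/output for per-SNP genotype count tables and result tables.

Input format: tab-separated, UTF-8, '.' decimal, header
``snp  r0  r1  r2  s0  s1  s2`` — one row per marker, integer counts.
Degenerate (monomorphic) markers are kept but flagged; the CLI reports them
as NA rows instead of aborting a batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .contingency import GenotypeCounts

__all__ = ["CountsTable", "read_counts", "write_results"]

log = logging.getLogger("robustgwas")

_COUNT_COLS = ["r0", "r1", "r2", "s0", "s1", "s2"]
_HEADER = ["snp"] + _COUNT_COLS


@dataclass
class CountsTable:
    """Ordered SNP -> GenotypeCounts mapping with provenance."""

    records: "dict[str, GenotypeCounts]"
    source: str = ""
    stage: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.items())

    def degenerate_ids(self) -> list[str]:
        return [snp for snp, c in self.records.items() if c.is_degenerate]


def read_counts(path, stage: str = "") -> CountsTable:
    """Read and validate a genotype counts TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != _HEADER:
        raise ValueError(
            f"{path}: expected header {_HEADER}, found {list(df.columns)}"
        )
    records: dict[str, GenotypeCounts] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        snp = row.snp
        if snp in records:
            raise ValueError(f"{path}: line {i}: duplicate SNP id {snp!r}")
        vals = []
        for col in _COUNT_COLS:
            raw = getattr(row, col)
            try:
                v = int(raw)
            except ValueError:
                raise ValueError(
                    f"{path}: line {i}: column {col} is not an integer: {raw!r}"
                ) from None
            if v < 0:
                raise ValueError(f"{path}: line {i}: negative count in {col}: {v}")
            vals.append(v)
        records[snp] = GenotypeCounts(*vals)
    if not records:
        log.warning("%s: no data rows", path)
    table = CountsTable(records, source=str(path), stage=stage)
    for snp in table.degenerate_ids():
        log.warning("%s: marker %s is degenerate (monomorphic)", path, snp)
    return table


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    if isinstance(v, float):
        return f"{v:.5e}"  # 6 significant digits, scientific
    return str(v)


def write_results(results: Iterable[Mapping], path, columns: list[str]) -> None:
    """Write result rows as TSV with deterministic column order.

    Floats are rendered in scientific notation with 6 significant digits;
    missing values (degenerate markers) as NA.
    """
    if results is None:
        raise ValueError("results must not be None")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in results:
            fh.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")
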