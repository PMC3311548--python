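"""Taxon-by-replicate count tables and derived proportion structures.

Counts are integers; proportions are computed per replicate by normalizing
each column, and "grand" proportions pool the raw counts across replicates
before normalizing (pooling, not averaging — the two differ whenever depths
differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .community_model import MockCommunity, ProportionVector

__all__ = [
    "ReplicateMeta",
    "CountTable",
    "CountTableError",
    "observed_proportions",
    "grand_proportions",
    "read_count_table",
    "write_count_table",
]


class CountTableError(ValueError):
    """Raised on malformed or inconsistent count tables."""


@dataclass(frozen=True)
class ReplicateMeta:
    """Identity and blocking labels for one replicate column."""

    replicate_id: str
    method: str = ""
    experimenter: str = ""
    day: str = ""


@dataclass(frozen=True)
class CountTable:
    """Non-negative integer counts, taxa as rows, replicates as columns."""

    taxa: tuple[str, ...]
    counts: np.ndarray = field(repr=False)
    meta: tuple[ReplicateMeta, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise CountTableError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape[0] != len(self.taxa):
            raise CountTableError(
                f"{len(self.taxa)} taxa but {counts.shape[0]} count rows"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if not np.array_equal(as_int, counts):
                raise CountTableError("counts must be integers")
            counts = as_int
        if np.any(counts < 0):
            r, c = np.argwhere(counts < 0)[0]
            raise CountTableError(
                f"negative count at taxon {self.taxa[r]!r}, column {c}"
            )
        object.__setattr__(self, "counts", counts)
        meta = tuple(self.meta)
        if not meta:
            meta = tuple(
                ReplicateMeta(replicate_id=f"r{j + 1}") for j in range(counts.shape[1])
            )
        if len(meta) != counts.shape[1]:
            raise CountTableError(
                f"{counts.shape[1]} columns but {len(meta)} metadata records"
            )
        ids = [m.replicate_id for m in meta]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise CountTableError(f"duplicate replicate ids: {', '.join(dupes)}")
        object.__setattr__(self, "meta", meta)

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[1]

    @property
    def replicate_ids(self) -> tuple[str, ...]:
        return tuple(m.replicate_id for m in self.meta)

    @property
    def depths(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def column(self, replicate_id: str) -> np.ndarray:
        return self.counts[:, self.replicate_ids.index(replicate_id)]

    def select(self, indices: Sequence[int]) -> "CountTable":
        idx = list(indices)
        return CountTable(
            self.taxa, self.counts[:, idx], tuple(self.meta[j] for j in idx)
        )

    def validate_against(self, community: MockCommunity) -> None:
        if self.taxa != community.names:
            raise CountTableError(
                "count-table taxa do not match the community "
                f"({list(self.taxa)[:3]}... vs {list(community.names)[:3]}...)"
            )


def observed_proportions(table: CountTable) -> list[ProportionVector]:
    """Per-replicate proportions: each column divided by its total."""
    totals = table.depths
    if np.any(totals == 0):
        bad = table.replicate_ids[int(np.argmax(totals == 0))]
        raise CountTableError(f"replicate {bad!r} has zero total reads")
    return [
        ProportionVector(table.taxa, table.counts[:, j] / totals[j])
        for j in range(table.n_replicates)
    ]


def grand_proportions(table: CountTable) -> ProportionVector:
    """Pool counts across replicates, then normalize (not a mean of columns)."""
    if table.n_replicates == 0:
        raise CountTableError("cannot pool an empty table")
    pooled = table.counts.sum(axis=1)
    total = pooled.sum()
    if total == 0:
        raise CountTableError("table contains no reads")
    return ProportionVector(table.taxa, pooled / total)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """TSV with ``#meta`` header lines followed by a taxon x replicate matrix."""
    lines = [
        f"#meta\t{m.replicate_id}\t{m.method}\t{m.experimenter}\t{m.day}"
        for m in table.meta
    ]
    lines.append("taxon\t" + "\t".join(table.replicate_ids))
    for i, taxon in enumerate(table.taxa):
        lines.append(taxon + "\t" + "\t".join(str(int(c)) for c in table.counts[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_count_table(
    path: str | Path, community: MockCommunity | None = None
) -> CountTable:
    """Inverse of :func:`write_count_table`; optionally checks taxa labels."""
    path = Path(path)
    meta_by_id: dict[str, ReplicateMeta] = {}
    matrix_lines: list[str] = []
    for ln in path.read_text().splitlines():
        if not ln.strip():
            continue
        if ln.startswith("#meta\t"):
            parts = ln.split("\t")
            if len(parts) != 5:
                raise CountTableError(f"{path}: malformed meta line {ln!r}")
            _, rid, method, experimenter, day = parts
            meta_by_id[rid] = ReplicateMeta(rid, method, experimenter, day)
        elif ln.startswith("#"):
            continue
        else:
            matrix_lines.append(ln)
    if not matrix_lines:
        raise CountTableError(f"{path}: no count matrix found")
    header = matrix_lines[0].split("\t")
    if header[0] != "taxon":
        raise CountTableError(f"{path}: first matrix column must be 'taxon'")
    replicate_ids = header[1:]
    taxa: list[str] = []
    rows: list[list[int]] = []
    for ln in matrix_lines[1:]:
        parts = ln.split("\t")
        if len(parts) != len(header):
            raise CountTableError(
                f"{path}: row {parts[0]!r} has {len(parts) - 1} cells, "
                f"expected {len(replicate_ids)}"
            )
        taxa.append(parts[0])
        row = []
        for rid, cell in zip(replicate_ids, parts[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise CountTableError(
                    f"{path}: non-integer count {cell!r} at taxon {parts[0]!r}, "
                    f"replicate {rid!r}"
                ) from None
            if value < 0:
                raise CountTableError(
                    f"{path}: negative count at taxon {parts[0]!r}, replicate {rid!r}"
                )
            row.append(value)
        rows.append(row)
    meta = tuple(
        meta_by_id.get(rid, ReplicateMeta(replicate_id=rid)) for rid in replicate_ids
    )
    table = CountTable(tuple(taxa), np.array(rows, dtype=np.int64), meta)
    if community is not None:
        table.validate_against(community)
    return table
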