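"""Mock-community definitions and copy-number-aware expected read proportions.

A mock community is an ordered list of taxa, each with a 16S rRNA gene copy
number and a (possibly unnormalized) relative cell abundance.  Under unbiased
extraction and amplification the expected share of 16S reads for taxon *i* is

    pi_i = c_i * g_i / sum_j c_j * g_j

with ``c`` the cell fraction and ``g`` the gene copy number.  All internal
math is done on fractions; percentages (one decimal, round half up) appear
only in formatted reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TaxonSpec",
    "MockCommunity",
    "ProportionVector",
    "DegenerateCommunityError",
    "CommunityValidationError",
    "expected_proportions",
    "load_community",
    "write_community",
    "round_half_up",
    "format_percent",
]


class CommunityValidationError(ValueError):
    """Raised when a community specification violates its invariants."""


class DegenerateCommunityError(ValueError):
    """Raised when every cell fraction in a community is zero."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_percent(fraction: float, ndigits: int = 1) -> float:
    """Present a fraction as a percentage rounded half-up to ``ndigits``."""
    return round_half_up(100.0 * fraction, ndigits)


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: a name, a 16S copy number and a cell fraction."""

    name: str
    copy_number: int
    cell_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not self.name:
            raise CommunityValidationError("taxon name must be non-empty")
        if not isinstance(self.copy_number, (int, np.integer)) or isinstance(
            self.copy_number, bool
        ):
            raise CommunityValidationError(
                f"copy_number for {self.name!r} must be an integer, "
                f"got {self.copy_number!r}"
            )
        if self.copy_number < 1:
            raise CommunityValidationError(
                f"copy_number for {self.name!r} must be >= 1, got {self.copy_number}"
            )
        if not np.isfinite(self.cell_fraction) or self.cell_fraction < 0:
            raise CommunityValidationError(
                f"cell_fraction for {self.name!r} must be finite and >= 0, "
                f"got {self.cell_fraction}"
            )


@dataclass(frozen=True)
class MockCommunity:
    """An ordered collection of taxa; the order fixes vector indexing downstream."""

    taxa: tuple[TaxonSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if len(self.taxa) == 0:
            raise CommunityValidationError("community must contain at least one taxon")
        names = [t.name for t in self.taxa]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise CommunityValidationError(f"duplicate taxon names: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.taxa)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.taxa)

    @property
    def copy_numbers(self) -> np.ndarray:
        return np.array([t.copy_number for t in self.taxa], dtype=float)

    @property
    def cell_fractions(self) -> np.ndarray:
        return np.array([t.cell_fraction for t in self.taxa], dtype=float)


@dataclass(frozen=True)
class ProportionVector:
    """A composition over the taxa of a community; entries sum to one."""

    taxa: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    _SUM_TOL = 1e-9

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.shape[0] != len(self.taxa):
            raise ValueError(
                f"values must be a 1-D vector of length {len(self.taxa)}, "
                f"got shape {values.shape}"
            )
        if np.any(values < -self._SUM_TOL) or np.any(values > 1 + self._SUM_TOL):
            raise ValueError("proportions must lie in [0, 1]")
        total = float(values.sum())
        if abs(total - 1.0) > self._SUM_TOL:
            raise ValueError(f"proportions must sum to 1 (got {total!r})")

    def __len__(self) -> int:
        return len(self.taxa)

    def __getitem__(self, name: str) -> float:
        try:
            return float(self.values[self.taxa.index(name)])
        except ValueError:
            raise KeyError(name) from None

    def as_percent(self, ndigits: int = 1) -> dict[str, float]:
        """Formatted view: percentages rounded half-up, keyed by taxon."""
        return {t: format_percent(v, ndigits) for t, v in zip(self.taxa, self.values)}

    def check_taxa(self, other: "ProportionVector" | Sequence[str]) -> None:
        other_taxa = other.taxa if isinstance(other, ProportionVector) else tuple(other)
        if self.taxa != other_taxa:
            raise ValueError(
                "taxa labels do not match: "
                f"{list(self.taxa)[:3]}... vs {list(other_taxa)[:3]}..."
            )


def expected_proportions(community: MockCommunity) -> ProportionVector:
    """Expected 16S read proportions: cell fractions weighted by copy numbers."""
    weights = community.cell_fractions * community.copy_numbers
    total = weights.sum()
    if total <= 0:
        raise DegenerateCommunityError(
            "all cell fractions are zero; expected proportions are undefined"
        )
    return ProportionVector(community.names, weights / total)


def _community_from_records(records: Iterable[dict], source: str) -> MockCommunity:
    taxa: list[TaxonSpec] = []
    seen: set[str] = set()
    for row_no, rec in enumerate(records, start=1):
        name = str(rec.get("name", "") or "").strip()
        if not name:
            raise CommunityValidationError(f"{source}, row {row_no}: missing taxon name")
        if name in seen:
            raise CommunityValidationError(
                f"{source}, row {row_no}: duplicate taxon name {name!r}"
            )
        seen.add(name)
        raw_copy = rec.get("copy_number")
        try:
            copy_number = int(str(raw_copy))
            if float(str(raw_copy)) != copy_number:
                raise ValueError
        except (TypeError, ValueError):
            raise CommunityValidationError(
                f"{source}, row {row_no} ({name}): copy_number must be a "
                f"positive integer, got {raw_copy!r}"
            ) from None
        raw_frac = rec.get("cell_fraction", 1.0)
        if raw_frac in ("", None):
            raw_frac = 1.0
        try:
            cell_fraction = float(raw_frac)
        except (TypeError, ValueError):
            raise CommunityValidationError(
                f"{source}, row {row_no} ({name}): cell_fraction must be a "
                f"number, got {raw_frac!r}"
            ) from None
        if cell_fraction < 0:
            raise CommunityValidationError(
                f"{source}, row {row_no} ({name}): negative cell_fraction "
                f"{cell_fraction!r}"
            )
        taxa.append(TaxonSpec(name, copy_number, cell_fraction))
    if not taxa:
        raise CommunityValidationError(f"{source}: no taxa found")
    return MockCommunity(tuple(taxa))


def load_community(path: str | Path, format: str | None = None) -> MockCommunity:
    """Read a community from TSV (``name  copy_number  cell_fraction``) or JSON.

    The file order defines the taxa order.  ``cell_fraction`` may be omitted
    (defaults to 1).  The format is inferred from the suffix unless given.
    """
    path = Path(path)
    fmt = (format or ("json" if path.suffix.lower() == ".json" else "tsv")).lower()
    if fmt == "json":
        payload = json.loads(path.read_text())
        records = payload["taxa"] if isinstance(payload, dict) else payload
        return _community_from_records(records, str(path))
    if fmt != "tsv":
        raise ValueError(f"unknown community format {fmt!r}")
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise CommunityValidationError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if "name" not in header or "copy_number" not in header:
        raise CommunityValidationError(
            f"{path}: header must contain 'name' and 'copy_number', got {header}"
        )
    records = []
    for ln in lines[1:]:
        fields = ln.rstrip("\n").split("\t")
        records.append(dict(zip(header, fields)))
    return _community_from_records(records, str(path))


def write_community(community: MockCommunity, path: str | Path) -> None:
    """Write a community as TSV (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "taxa": [
                {
                    "name": t.name,
                    "copy_number": t.copy_number,
                    "cell_fraction": t.cell_fraction,
                }
                for t in community.taxa
            ]
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    rows = ["name\tcopy_number\tcell_fraction"]
    for t in community.taxa:
        rows.append(f"{t.name}\t{t.copy_number}\t{t.cell_fraction:g}")
    path.write_text("\n".join(rows) + "\n")
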