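"""Self-contained amplicon read QC: demultiplexing, primer matching, filters.

Reads are modelled as barcode + linker + forward primer + template.  A read
is kept iff it demultiplexes uniquely within the barcode Hamming budget, the
(IUPAC-degenerate) primer matches within the mismatch budget, and the
trimmed template passes length, ambiguity and homopolymer thresholds.  Every
rejection records the first failing rule; filter order only affects the
logged reason, never the kept set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "AmpliconRead",
    "PrimerSet",
    "FilterPolicy",
    "FilterResult",
    "assign_barcode",
    "match_primer",
    "longest_homopolymer",
    "hamming_distance",
    "filter_reads",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "read_barcode_map",
]

_DNA_ALPHABET = set("ACGTN")
_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

FILTER_ORDER = ("barcode", "primer", "length", "ambiguity", "homopolymer")


@dataclass(frozen=True)
class AmpliconRead:
    """One read: id, uppercase DNA over {A,C,G,T,N}, optional quality."""

    id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"read {self.id!r}: invalid characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )
        if self.quality is not None and len(self.quality) != len(seq):
            raise ValueError(f"read {self.id!r}: quality length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerSet:
    """Named IUPAC-degenerate primers (e.g. 27f-CM = AGAGTTTGATCMTGGCTCAG)."""

    primers: dict[str, str]

    def __post_init__(self) -> None:
        if not self.primers:
            raise ValueError("primer set must be non-empty")
        for label, seq in self.primers.items():
            bad = set(seq.upper()) - set(_IUPAC)
            if not seq or bad:
                raise ValueError(
                    f"primer {label!r}: invalid IUPAC sequence {seq!r}"
                )
        object.__setattr__(
            self, "primers", {k: v.upper() for k, v in self.primers.items()}
        )


@dataclass(frozen=True)
class FilterPolicy:
    """Thresholds for the keep/reject rules (defaults mirror 454-era QC)."""

    min_length: int = 100
    max_barcode_hamming: int = 1
    max_primer_mismatch: int = 2
    max_ambiguous: int = 1       # keep iff count(N) <= 1, i.e. "< 2"
    max_homopolymer: int = 6     # keep iff longest run <= 6, i.e. "< 7"
    linker: str = "TC"

    def __post_init__(self) -> None:
        for name in (
            "min_length",
            "max_barcode_hamming",
            "max_primer_mismatch",
            "max_ambiguous",
            "max_homopolymer",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def hamming_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def assign_barcode(
    observed: str, barcodes: dict[str, str], max_dist: int = 1
) -> str | None:
    """Label of the unique barcode within ``max_dist`` of the read prefix.

    Returns None when no barcode, or more than one, is in range — ambiguity
    is never guessed.
    """
    if not barcodes:
        raise ValueError("no barcodes supplied")
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValueError("all barcodes must share one length")
    bc_len = lengths.pop()
    observed = observed.upper()
    if len(observed) < bc_len:
        return None
    prefix = observed[:bc_len]
    hits = [
        label
        for label, bc in barcodes.items()
        if hamming_distance(prefix, bc.upper()) <= max_dist
    ]
    return hits[0] if len(hits) == 1 else None


def _iupac_mismatches(sequence: str, primer: str) -> int:
    return sum(base not in _IUPAC[code] for base, code in zip(sequence, primer))


def match_primer(
    sequence: str, primers: PrimerSet, max_mismatch: int = 2
) -> dict:
    """Best IUPAC-aware primer match at position 0 of ``sequence``.

    A degenerate code matches any base of its expansion at zero cost.  An N
    in the read counts as a mismatch unless the primer position is N.
    """
    sequence = sequence.upper()
    best_label, best_mm = None, None
    for label, primer in primers.primers.items():
        if len(primer) > len(sequence):
            continue
        mm = _iupac_mismatches(sequence[: len(primer)], primer)
        if best_mm is None or mm < best_mm:
            best_label, best_mm = label, mm
    if best_mm is None:
        return {"matched": False, "primer": None, "mismatches": None}
    return {
        "matched": best_mm <= max_mismatch,
        "primer": best_label,
        "mismatches": best_mm,
    }


def longest_homopolymer(sequence: str) -> int:
    """Length of the longest single-base run."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    best = run = 1
    for prev, cur in zip(sequence, sequence[1:]):
        run = run + 1 if cur == prev else 1
        best = max(best, run)
    return best


@dataclass
class FilterResult:
    """Kept reads (trimmed) plus a per-read rejection log."""

    kept: list[AmpliconRead] = field(default_factory=list)
    rejections: dict[str, str] = field(default_factory=dict)
    assignments: dict[str, str] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejections)


def filter_reads(
    reads: Iterable[AmpliconRead],
    barcodes: dict[str, str] | None,
    primers: PrimerSet | None,
    policy: FilterPolicy = FilterPolicy(),
    external_pass: dict[str, bool] | None = None,
) -> FilterResult:
    """Apply the keep/reject rules; kept reads are trimmed to the template.

    Stages run as barcode, primer, length, ambiguity, homopolymer; the first
    failure is logged.  Passing ``barcodes=None`` (or ``primers=None``)
    disables that stage and its trimming, so already-trimmed reads can be
    re-filtered.  ``external_pass`` hooks in per-read verdicts from filters
    implemented elsewhere (e.g. alignment-position criteria).
    """
    result = FilterResult()
    bc_len = 0
    if barcodes:
        lengths = {len(b) for b in barcodes.values()}
        if len(lengths) != 1:
            raise ValueError("all barcodes must share one length")
        bc_len = lengths.pop()
    for read in reads:
        label = None
        seq = read.sequence
        qual = read.quality
        if barcodes:
            label = assign_barcode(seq, barcodes, policy.max_barcode_hamming)
            if label is None:
                result.rejections[read.id] = "barcode"
                continue
            cut = bc_len + len(policy.linker)
            seq, qual = seq[cut:], qual[cut:] if qual else None
        if primers:
            hit = match_primer(seq, primers, policy.max_primer_mismatch)
            if not hit["matched"]:
                result.rejections[read.id] = "primer"
                continue
            cut = len(primers.primers[hit["primer"]])
            seq, qual = seq[cut:], qual[cut:] if qual else None
        if len(seq) < policy.min_length:
            result.rejections[read.id] = "length"
            continue
        if seq.count("N") > policy.max_ambiguous:
            result.rejections[read.id] = "ambiguity"
            continue
        if longest_homopolymer(seq) > policy.max_homopolymer:
            result.rejections[read.id] = "homopolymer"
            continue
        if external_pass is not None and not external_pass.get(read.id, True):
            result.rejections[read.id] = "external"
            continue
        trimmed = replace(read, sequence=seq, quality=tuple(qual) if qual else None)
        result.kept.append(trimmed)
        if label is not None:
            result.assignments[read.id] = label
    return result


def read_fastq(path: str | Path) -> Iterator[AmpliconRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield AmpliconRead(
            rec.id,
            str(rec.seq),
            tuple(rec.letter_annotations["phred_quality"]),
        )


def read_fasta(path: str | Path) -> Iterator[AmpliconRead]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield AmpliconRead(rec.id, str(rec.seq))


def write_fastq(reads: Iterable[AmpliconRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            qual = read.quality or tuple([40] * len(read))
            qline = "".join(chr(q + 33) for q in qual)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{qline}\n")
            n += 1
    return n


def write_fasta(reads: Iterable[AmpliconRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f">{read.id}\n{read.sequence}\n")
            n += 1
    return n


def read_barcode_map(path: str | Path) -> dict[str, str]:
    """TSV ``label<TAB>barcode`` (a header line is tolerated)."""
    barcodes: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) != 2:
            raise ValueError(f"malformed barcode line {ln!r}")
        label, bc = parts
        if label.lower() == "label" and set(bc.upper()) - _DNA_ALPHABET:
            continue
        barcodes[label] = bc.upper()
    if not barcodes:
        raise ValueError("no barcodes found")
    return barcodes
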