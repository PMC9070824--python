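"""Sequence and interval I/O: contig registry, GC composition, FASTA/BED.

Coordinates are 0-based half-open everywhere, matching BED. Input
sequences are uppercased; characters outside ``{A, C, G, T, N}`` are
rejected at parse time. N bases are excluded from the GC denominator
and never participate in any motif match downstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

__all__ = [
    "VALID_BASES",
    "Contig",
    "GenomeAssembly",
    "Interval",
    "revcomp",
    "gc_fraction",
    "read_fasta",
    "write_fasta",
    "write_bed",
    "read_bed",
    "assembly_summary",
]

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of *seq* (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """(#G + #C) / (#non-N bases); 0.0 when there are no non-N bases.

    Raises ``ValueError`` on an empty string.
    """
    if not seq:
        raise ValueError("gc_fraction of empty sequence is undefined")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        return 0.0
    return gc / denom


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence; the unit of every scan in the pipeline."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - VALID_BASES
        if bad:
            offset = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"illegal character {self.seq[offset]!r} in contig "
                f"{self.id!r} at offset {offset}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        """GC fraction over non-N bases (0.0 for an all-N contig)."""
        return gc_fraction(self.seq) if self.seq else 0.0

    @property
    def all_n(self) -> bool:
        """True when the contig contains no non-N base."""
        return len(self.seq) > 0 and len(self.seq) == self.seq.count("N")


@dataclass(frozen=True)
class Interval:
    """A strand-aware half-open interval on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on "
                f"{self.contig_id!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAssembly:
    """Ordered contig collection with designated centromere contigs."""

    contigs: list[Contig] = field(default_factory=list)
    centromere_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate contig id {dup!r}")
        unknown = self.centromere_ids - set(ids)
        if unknown:
            raise ValueError(f"centromere ids not in assembly: {sorted(unknown)}")
        self._by_id = {c.id: c for c in self.contigs}

    def __len__(self) -> int:
        return len(self.contigs)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._by_id

    def __getitem__(self, contig_id: str) -> Contig:
        try:
            return self._by_id[contig_id]
        except KeyError:
            raise KeyError(f"unknown contig {contig_id!r}") from None

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def background_contigs(self) -> list[Contig]:
        """Contigs not designated as centromeres."""
        return [c for c in self.contigs if c.id not in self.centromere_ids]

    def fetch(self, iv: Interval) -> str:
        """Sequence of *iv* (plus strand as stored)."""
        contig = self[iv.contig_id]
        if iv.end > contig.length:
            raise ValueError(
                f"interval [{iv.start}, {iv.end}) exceeds contig "
                f"{contig.id!r} length {contig.length}"
            )
        return contig.seq[iv.start : iv.end]


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path, centromere_ids: Iterable[str] = ()) -> GenomeAssembly:
    """Parse a (possibly gzipped) FASTA file into a :class:`GenomeAssembly`.

    Duplicate headers and characters outside ``{A,C,G,T,N}`` are errors.
    The header is truncated at the first whitespace, as is conventional.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    contigs: list[Contig] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if name is None:
            return
        contigs.append(Contig(name, "".join(chunks)))

    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise ValueError(f"empty FASTA header in {path}")
                if name in seen:
                    raise ValueError(f"duplicate FASTA header {name!r} in {path}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"sequence before first header in {path}")
                chunks.append(line)
        flush()
    return GenomeAssembly(contigs, set(centromere_ids))


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in assembly.contigs:
            fh.write(f">{contig.id}\n")
            for i in range(0, contig.length, width):
                fh.write(contig.seq[i : i + width] + "\n")


def _bed_score(record) -> tuple[int, str | None]:
    """BED score column scaled to 0..1000 plus optional raw value."""
    stars = getattr(record, "stars", None)
    if stars is not None:
        return round(stars / 3 * 1000), str(stars)
    score = getattr(record, "score", None)
    if score is not None:
        capped = min(abs(float(score)) / 4.0, 1.0)
        return round(capped * 1000), f"{float(score):.2f}"
    return 0, None


def write_bed(
    records: Sequence,
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    name_fn: Callable | None = None,
) -> None:
    """Write interval-like records as BED6, raw value in column 7 when present.

    Each record must expose an ``interval`` attribute or itself be an
    :class:`Interval`. If *assembly* is given, contig ids are validated.
    """
    lines = []
    for rec in records:
        iv = getattr(rec, "interval", rec)
        if assembly is not None and iv.contig_id not in assembly:
            raise KeyError(f"unknown contig {iv.contig_id!r}")
        if name_fn is not None:
            name = name_fn(rec)
        else:
            name = getattr(rec, "motif_class", None) or getattr(rec, "name", ".")
        score, raw = _bed_score(rec)
        cols = [iv.contig_id, str(iv.start), str(iv.end), str(name), str(score), iv.strand]
        if raw is not None:
            cols.append(raw)
        lines.append("\t".join(cols))
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")


def read_bed(path: str | Path) -> Iterator[Interval]:
    """Yield Intervals from a BED3+ file (extra columns ignored)."""
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            yield Interval(fields[0], int(fields[1]), int(fields[2]), strand)


def assembly_summary(assembly: GenomeAssembly) -> list[dict]:
    """One row per contig: id, length, gc, all_n flag, centromere flag."""
    return [
        {
            "id": c.id,
            "length": c.length,
            "gc": c.gc,
            "all_n": c.all_n,
            "is_centromere": c.id in assembly.centromere_ids,
        }
        for c in assembly.contigs
    ]
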