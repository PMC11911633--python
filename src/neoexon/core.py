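"""Core data model shared by every analysis stage.

Genomic coordinates are 0-based, half-open throughout the package.  GTF
input/output converts to and from the 1-based inclusive convention at the
file boundary only (see :mod:`neoexon.io`).  Minus-strand transcripts store
their exons in genomic order; transcription order is computed on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_ALPHABET = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class BoundsError(ValueError):
    """Raised when an interval reaches outside its sequence."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A, C, G, T, N}, stored uppercase."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("sequence name must be non-empty")
        if not self.seq:
            raise FormatError(f"sequence {self.name!r} is empty")
        up = self.seq.upper()
        bad = set(up) - VALID_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.name!r} contains invalid characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", up)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    seq_name: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_name}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "Interval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start <= other.start
            and other.end <= self.end
        )


def extract_sequence(genome: GenomeSequence, iv: Interval) -> str:
    """Sequence of ``iv``: substring on '+', reverse complement on '-'."""
    if iv.seq_name != genome.name:
        raise BoundsError(
            f"interval on {iv.seq_name!r} does not match sequence {genome.name!r}"
        )
    if iv.end > len(genome):
        raise BoundsError(
            f"interval [{iv.start}, {iv.end}) exceeds length {len(genome)} of {genome.name}"
        )
    sub = genome.seq[iv.start : iv.end]
    return sub if iv.strand == "+" else reverse_complement(sub)


@dataclass
class Transcript:
    """A transcript: ordered exons on one strand, optionally with a CDS.

    Exons are stored in genomic order (ascending start) regardless of
    strand; ``exons_transcription_order`` gives biological 5'→3' order.
    """

    id: str
    gene_id: str
    exons: list[Interval]
    cds: list[Interval] | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        seqs = {e.seq_name for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(seqs) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.id} spans sequences/strands")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.id} has overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if self.cds:
            self.cds = sorted(self.cds, key=lambda c: c.start)
            if self.cds_length % 3 != 0:
                raise ValueError(
                    f"transcript {self.id}: CDS length {self.cds_length} "
                    "not divisible by 3"
                )

    @property
    def seq_name(self) -> str:
        return self.exons[0].seq_name

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> Interval:
        return Interval(
            self.seq_name, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def cds_length(self) -> int:
        return sum(len(c) for c in self.cds) if self.cds else 0

    def exons_transcription_order(self) -> list[Interval]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns(self) -> list[Interval]:
        """Introns in genomic order."""
        return [
            Interval(self.seq_name, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]

    def boundaries(self) -> set[int]:
        out: set[int] = set()
        for e in self.exons:
            out.add(e.start)
            out.add(e.end)
        return out


@dataclass
class Gene:
    gene_id: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)
    biotype: str = "protein_coding"

    @property
    def seq_name(self) -> str:
        return next(iter(self.transcripts.values())).seq_name

    @property
    def strand(self) -> str:
        return next(iter(self.transcripts.values())).strand

    @property
    def interval(self) -> Interval:
        spans = [t.span for t in self.transcripts.values()]
        return Interval(
            self.seq_name,
            min(s.start for s in spans),
            max(s.end for s in spans),
            self.strand,
        )

    def boundary_index(self) -> set[int]:
        """Union of exon start/end coordinates over all transcripts."""
        out: set[int] = set()
        for t in self.transcripts.values():
            out |= t.boundaries()
        return out

    def exon_union(self) -> list[Interval]:
        """Merged exonic intervals of the gene, genomic order."""
        exons = sorted(
            (e for t in self.transcripts.values() for e in t.exons),
            key=lambda e: e.start,
        )
        merged: list[list[int]] = []
        for e in exons:
            if merged and e.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e.end)
            else:
                merged.append([e.start, e.end])
        return [Interval(self.seq_name, s, t, self.strand) for s, t in merged]

    def intron_union(self) -> list[Interval]:
        """Gaps between merged exon blocks (genic, non-exonic regions)."""
        blocks = self.exon_union()
        return [
            Interval(self.seq_name, a.end, b.start, self.strand)
            for a, b in zip(blocks, blocks[1:])
        ]


class GeneAnnotation:
    """Gene → transcript → exon hierarchy with boundary lookups."""

    def __init__(self, genes: Iterable[Gene] = ()) -> None:
        self.genes: dict[str, Gene] = {}
        for g in genes:
            self.add_gene(g)

    def add_gene(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene id {gene.gene_id}")
        self.genes[gene.gene_id] = gene

    def add_transcript(self, tx: Transcript, biotype: str = "protein_coding") -> None:
        gene = self.genes.setdefault(tx.gene_id, Gene(tx.gene_id, biotype=biotype))
        gene.transcripts[tx.id] = tx

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def transcripts(self) -> Iterator[Transcript]:
        for g in self:
            yield from g.transcripts.values()

    def genes_overlapping(self, iv: Interval, same_strand: bool = True) -> list[Gene]:
        out = []
        for g in self:
            gi = g.interval
            if gi.seq_name == iv.seq_name and gi.start < iv.end and iv.start < gi.end:
                if not same_strand or g.strand == iv.strand:
                    out.append(g)
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneAnnotation):
            return NotImplemented
        if set(self.genes) != set(other.genes):
            return False
        for gid, g in self.genes.items():
            og = other.genes[gid]
            if set(g.transcripts) != set(og.transcripts):
                return False
            for tid, t in g.transcripts.items():
                ot = og.transcripts[tid]
                if t.exons != ot.exons or (t.cds or []) != (ot.cds or []):
                    return False
        return True


class CoverageTrack:
    """Dense per-base read depth over named sequences."""

    def __init__(self, depths: Mapping[str, np.ndarray]) -> None:
        self.depths: dict[str, np.ndarray] = {}
        for name, arr in depths.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 1:
                raise ValueError(f"depth array for {name} must be 1-D")
            if (a < 0).any():
                raise ValueError(f"negative depth on {name}")
            self.depths[name] = a

    @classmethod
    def zeros(cls, sequences: Iterable[GenomeSequence]) -> "CoverageTrack":
        return cls({s.name: np.zeros(len(s)) for s in sequences})

    def mean_depth(self, iv: Interval) -> float:
        """Arithmetic mean depth over the interval."""
        arr = self._slice(iv)
        return float(arr.mean())

    def _slice(self, iv: Interval) -> np.ndarray:
        if iv.seq_name not in self.depths:
            raise BoundsError(f"no coverage for sequence {iv.seq_name!r}")
        arr = self.depths[iv.seq_name]
        if iv.end > len(arr):
            raise BoundsError(
                f"interval [{iv.start},{iv.end}) exceeds {iv.seq_name} length {len(arr)}"
            )
        return arr[iv.start : iv.end]


JunctionKey = tuple[str, int, int, str]  # (seq_name, intron_start, intron_end, strand)


class JunctionCounts:
    """Per-sample split-read counts keyed by intron interval.

    Keys are ``(seq_name, donor_pos, acceptor_pos, strand)`` where the
    positions delimit the 0-based half-open intron.
    """

    def __init__(self) -> None:
        self._counts: dict[JunctionKey, dict[str, int]] = {}

    @staticmethod
    def _check_key(key: JunctionKey) -> None:
        _, start, end, strand = key
        if not start < end:
            raise ValueError(f"junction donor {start} must precede acceptor {end}")
        if strand not in ("+", "-"):
            raise ValueError(f"bad strand {strand!r}")

    def add(self, key: JunctionKey, sample: str, count: int) -> None:
        self._check_key(key)
        if count < 0 or int(count) != count:
            raise ValueError(f"count must be a non-negative integer, got {count}")
        self._counts.setdefault(key, {})[sample] = (
            self._counts.get(key, {}).get(sample, 0) + int(count)
        )

    def get(self, key: JunctionKey, sample: str) -> int:
        return self._counts.get(key, {}).get(sample, 0)

    def samples(self) -> list[str]:
        out: set[str] = set()
        for per in self._counts.values():
            out |= set(per)
        return sorted(out)

    def keys(self) -> list[JunctionKey]:
        return sorted(self._counts)

    def __len__(self) -> int:
        return len(self._counts)


@dataclass
class CountMatrix:
    """Genes × samples integer counts with per-sample group labels."""

    counts: pd.DataFrame  # index: gene ids, columns: sample names
    groups: pd.Series  # index: sample names, values: group labels

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.groups.index):
            raise ValueError("count columns and group index must match in order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def subset_groups(self, group_a: str, group_b: str) -> "CountMatrix":
        keep = [s for s in self.counts.columns if self.groups[s] in (group_a, group_b)]
        return CountMatrix(self.counts[keep], self.groups[keep])


def gene_characteristics(annotation: GeneAnnotation) -> pd.DataFrame:
    """Per-gene structural characteristics.

    Returns one row per gene with the number of annotated transcripts, the
    genomic span, the maximal exon count over isoforms and the mean CDS
    length over coding isoforms (NaN for non-coding genes).
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    rows = []
    for gene in annotation:
        txs = list(gene.transcripts.values())
        cds_lengths = [t.cds_length for t in txs if t.cds]
        rows.append(
            {
                "gene_id": gene.gene_id,
                "n_transcripts": len(txs),
                "gene_length": len(gene.interval),
                "max_exons": max(len(t.exons) for t in txs),
                "mean_cds_length": float(np.mean(cds_lengths))
                if cds_lengths
                else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")
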