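"""Novel-exon discovery from assembled transcripts.

The procedure mirrors how unannotated exons are found in de-novo transcript
assemblies of RNA-seq data:

1. compare assembled transcripts to the reference annotation and keep
   internal exons with at least one boundary absent from the host gene's
   annotated exon-boundary set ("new-boundary" exons);
2. filter candidates by expression — mean per-base coverage strictly
   greater than 5 reads and at least 10-fold above the surrounding
   exon-masked intronic background;
3. remove candidates not framed by canonical splice sites (GT donor / AG
   acceptor on the transcribed strand).

Each candidate keeps a full per-filter audit trail.  The comparison of a
candidate's expression with its flanking exons is reported as a score but
never used as a filter, and the reading-frame consequence of splicing the
exon into an annotated CDS (premature stop, number of novel amino acids)
plus a cross-species identity scorer complete the characterization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .core import (
    CoverageTrack,
    Gene,
    GeneAnnotation,
    GenomeSequence,
    Interval,
    Transcript,
    extract_sequence,
)

log = logging.getLogger(__name__)

CANONICAL_PAIRS = frozenset({("GT", "AG")})


@dataclass(frozen=True)
class ThresholdConfig:
    """Filter thresholds of the candidate funnel.

    ``min_mean_coverage`` is applied strictly (> 5 reads); the background
    ratio is inclusive (>= 10-fold).  ``background_floor`` guards the ratio
    against an all-zero intronic background.
    """

    min_mean_coverage: float = 5.0
    min_background_ratio: float = 10.0
    background_window: int = 200
    background_floor: float = 0.1
    canonical_pairs: frozenset[tuple[str, str]] = CANONICAL_PAIRS

    def __post_init__(self) -> None:
        if min(self.min_mean_coverage, self.min_background_ratio) <= 0:
            raise ValueError("thresholds must be positive")
        if self.background_window <= 0 or self.background_floor <= 0:
            raise ValueError("background window and floor must be positive")
        if not self.canonical_pairs:
            raise ValueError("canonical_pairs must be non-empty")


FILTER_ORDER = ("coverage", "background_ratio", "canonical_sites")


@dataclass
class NovelExonCandidate:
    """An assembled exon with new boundaries and its filter audit trail."""

    interval: Interval
    host_gene: str
    transcript_id: str
    boundary_status: str  # "both_new" | "one_new"
    fully_novel: bool
    host_intron: Interval | None = None
    mean_coverage: float = float("nan")
    background_coverage: float = float("nan")
    background_ratio: float = float("nan")
    donor: str = ""
    acceptor: str = ""
    canonical: bool = False
    flanking_ratio: float = float("nan")
    filter_trail: list[tuple[str, bool]] = field(default_factory=list)
    verdict: bool = False


@dataclass
class OrfConsequence:
    """Effect of splicing a candidate exon into an annotated CDS."""

    frame_preserving: bool
    premature_stop: bool
    novel_aa_before_stop: int | None
    non_coding_region: bool = False


# ---------------------------------------------------------------------------
# Candidate detection

def _host_gene(reference: GeneAnnotation, exon: Interval) -> Gene | None:
    hits = reference.genes_overlapping(exon, same_strand=True)
    if not hits:
        return None
    # most-overlapping gene wins
    def overlap(g: Gene) -> int:
        gi = g.interval
        return min(gi.end, exon.end) - max(gi.start, exon.start)

    return max(hits, key=overlap)


def _enclosing_intron(gene: Gene, exon: Interval) -> Interval | None:
    for intron in gene.intron_union():
        if intron.contains(exon):
            return intron
    return None


def find_new_boundary_exons(
    assembled: GeneAnnotation, reference: GeneAnnotation
) -> list[NovelExonCandidate]:
    """Internal assembled exons with >= 1 boundary new to their host gene.

    Terminal exons of assembled transcripts are skipped (assembly end
    boundaries are unreliable); exons overlapping no same-strand reference
    gene are excluded as intergenic.  Candidates lying fully inside a
    reference intron with both boundaries new are flagged ``fully_novel``.
    """
    candidates: list[NovelExonCandidate] = []
    seen: set[tuple] = set()
    for tx in assembled.transcripts():
        for exon in tx.exons[1:-1]:
            host = _host_gene(reference, exon)
            if host is None:
                log.info("exon %s:%d-%d intergenic; excluded", exon.seq_name, exon.start, exon.end)
                continue
            boundaries = host.boundary_index()
            new_start = exon.start not in boundaries
            new_end = exon.end not in boundaries
            if not (new_start or new_end):
                continue
            key = (exon.seq_name, exon.start, exon.end, exon.strand, host.gene_id)
            if key in seen:
                continue
            seen.add(key)
            status = "both_new" if (new_start and new_end) else "one_new"
            intron = _enclosing_intron(host, exon)
            candidates.append(
                NovelExonCandidate(
                    interval=exon,
                    host_gene=host.gene_id,
                    transcript_id=tx.id,
                    boundary_status=status,
                    fully_novel=(status == "both_new" and intron is not None),
                    host_intron=intron,
                )
            )
    return candidates


# ---------------------------------------------------------------------------
# Coverage filters

def mean_exon_coverage(iv: Interval, track: CoverageTrack) -> float:
    """Arithmetic mean per-base depth over the interval."""
    if len(iv) == 0:
        raise ValueError("zero-length interval")
    return track.mean_depth(iv)


def _mask_exons(
    window: Interval, exons: list[Interval], arr: np.ndarray
) -> np.ndarray:
    keep = np.ones(len(window), dtype=bool)
    for e in exons:
        if e.seq_name != window.seq_name:
            continue
        lo = max(e.start, window.start) - window.start
        hi = min(e.end, window.end) - window.start
        if lo < hi:
            keep[lo:hi] = False
    return arr[keep]


def intronic_background(
    candidate: NovelExonCandidate,
    track: CoverageTrack,
    reference: GeneAnnotation,
    assembled: GeneAnnotation | None = None,
    config: ThresholdConfig = ThresholdConfig(),
) -> float:
    """Mean depth of exon-masked windows flanking the candidate.

    Up to ``background_window`` nt on each side, clipped to the host intron
    (or, for boundary-modifying candidates without one, to the host gene's
    span), with every reference or assembled exon overlapping the windows
    masked out.  Both windows are pooled base-wise.  Empty windows return
    the floor value.
    """
    exon = candidate.interval
    host = reference.genes[candidate.host_gene]
    bound = candidate.host_intron if candidate.host_intron is not None else host.interval
    w = config.background_window
    values: list[np.ndarray] = []
    mask_exons = [e for t in host.transcripts.values() for e in t.exons]
    if assembled is not None:
        mask_exons += [e for t in assembled.transcripts() for e in t.exons]
    mask_exons = [
        e for e in mask_exons if (e.start, e.end, e.seq_name) != (exon.start, exon.end, exon.seq_name)
    ]

    up_start = max(bound.start, exon.start - w)
    if up_start < exon.start:
        win = Interval(exon.seq_name, up_start, exon.start, exon.strand)
        values.append(_mask_exons(win, mask_exons, track._slice(win)))
    down_end = min(bound.end, exon.end + w)
    if exon.end < down_end:
        win = Interval(exon.seq_name, exon.end, down_end, exon.strand)
        values.append(_mask_exons(win, mask_exons, track._slice(win)))
    pooled = np.concatenate(values) if values else np.array([])
    if pooled.size == 0:
        log.warning(
            "candidate %s:%d-%d has no intronic background window; using floor",
            exon.seq_name, exon.start, exon.end,
        )
        return config.background_floor
    return float(pooled.mean())


# ---------------------------------------------------------------------------
# Splice sites

def splice_site_check(
    candidate: NovelExonCandidate,
    genome: GenomeSequence,
    config: ThresholdConfig = ThresholdConfig(),
) -> tuple[str, str, bool]:
    """Donor/acceptor dinucleotides flanking the exon, on the transcribed strand.

    The donor is read from the first two intronic bases 3' of the exon and
    the acceptor from the last two intronic bases 5' of it; on the minus
    strand both come from the reverse complement.
    """
    exon = candidate.interval
    if exon.start < 2 or exon.end + 2 > len(genome):
        raise ValueError("flank shorter than 2 nt; cannot read splice sites")
    left = Interval(exon.seq_name, exon.start - 2, exon.start, exon.strand)
    right = Interval(exon.seq_name, exon.end, exon.end + 2, exon.strand)
    if exon.strand == "+":
        acceptor = extract_sequence(genome, Interval(left.seq_name, left.start, left.end, "+"))
        donor = extract_sequence(genome, Interval(right.seq_name, right.start, right.end, "+"))
    else:
        donor = extract_sequence(genome, left)  # revcomp of upstream flank
        acceptor = extract_sequence(genome, right)
    canonical = (donor, acceptor) in config.canonical_pairs
    return donor, acceptor, canonical


# ---------------------------------------------------------------------------
# Filter funnel

def filter_candidates(
    candidates: list[NovelExonCandidate],
    track: CoverageTrack,
    genomes: dict[str, GenomeSequence],
    reference: GeneAnnotation,
    config: ThresholdConfig = ThresholdConfig(),
    assembled: GeneAnnotation | None = None,
) -> list[NovelExonCandidate]:
    """Apply the coverage → background-ratio → canonical-site funnel.

    Filters are evaluated in that order; every candidate keeps the full
    trail even after a failure, and the verdict passes only if all three
    filters do.
    """
    for cand in candidates:
        cand.mean_coverage = mean_exon_coverage(cand.interval, track)
        cand.background_coverage = intronic_background(
            cand, track, reference, assembled, config
        )
        cand.background_ratio = cand.mean_coverage / max(
            cand.background_coverage, config.background_floor
        )
        cand.donor, cand.acceptor, cand.canonical = splice_site_check(
            cand, genomes[cand.interval.seq_name], config
        )
        cand.flanking_ratio = flanking_exon_ratio(cand, track, reference)
        cand.filter_trail = [
            ("coverage", cand.mean_coverage > config.min_mean_coverage),
            ("background_ratio", cand.background_ratio >= config.min_background_ratio),
            ("canonical_sites", cand.canonical),
        ]
        cand.verdict = all(ok for _, ok in cand.filter_trail)
    return candidates


def funnel_counts(candidates: list[NovelExonCandidate]) -> dict[str, int]:
    """Cumulative survivor counts along the filter funnel."""
    counts = {"new_boundary": len(candidates)}
    surviving = candidates
    for name in FILTER_ORDER:
        surviving = [
            c for c in surviving if dict(c.filter_trail).get(name, False)
        ]
        counts[f"post_{name}"] = len(surviving)
    return counts


def flanking_exon_ratio(
    candidate: NovelExonCandidate,
    track: CoverageTrack,
    reference: GeneAnnotation,
) -> float:
    """Candidate mean depth over the mean of its two flanking exons' depths.

    Reported for manual review, never used as a filter.  NaN when the
    candidate has no host intron or both flanking exons are uncovered.
    """
    if candidate.host_intron is None:
        return float("nan")
    host = reference.genes[candidate.host_gene]
    blocks = host.exon_union()
    intron = candidate.host_intron
    left = next((b for b in blocks if b.end == intron.start), None)
    right = next((b for b in blocks if b.start == intron.end), None)
    if left is None or right is None:
        return float("nan")
    flank_means = [track.mean_depth(left), track.mean_depth(right)]
    denom = float(np.mean(flank_means))
    if denom == 0:
        return float("nan")
    return mean_exon_coverage(candidate.interval, track) / denom


# ---------------------------------------------------------------------------
# ORF consequence

def orf_consequence(
    candidate: NovelExonCandidate,
    host_transcript: Transcript,
    genome: GenomeSequence,
) -> OrfConsequence:
    """Reading-frame effect of splicing the candidate into the host CDS.

    The exon sequence is inserted into the mature CDS at its genomic
    position and the result translated from the annotated start.
    ``premature_stop`` marks a stop codon upstream of the original
    terminator; ``novel_aa_before_stop`` counts amino acids from the first
    codon altered by the insertion up to (excluding) the new stop.
    """
    if not host_transcript.cds:
        raise ValueError(f"transcript {host_transcript.id} has no annotated CDS")
    exon = candidate.interval
    cds = host_transcript.cds
    # candidate must fall between two consecutive CDS segments
    slot = None
    for i in range(len(cds) - 1):
        if cds[i].end <= exon.start and exon.end <= cds[i + 1].start:
            slot = i
            break
    if slot is None:
        return OrfConsequence(
            frame_preserving=False,
            premature_stop=False,
            novel_aa_before_stop=None,
            non_coding_region=True,
        )
    strand = host_transcript.strand
    if strand == "+":
        offset = sum(len(c) for c in cds[: slot + 1])
    else:
        offset = sum(len(c) for c in cds[slot + 1 :])
    cds_seq = "".join(
        extract_sequence(genome, c)
        for c in (cds if strand == "+" else list(reversed(cds)))
    )
    insert = extract_sequence(
        genome, Interval(exon.seq_name, exon.start, exon.end, strand)
    )
    modified = cds_seq[:offset] + insert + cds_seq[offset:]

    protein = str(Seq(modified[: len(modified) - len(modified) % 3]).translate())
    stop_idx = protein.find("*")
    orig_stop_nt = len(modified) - 3  # where the original terminator now sits
    premature = stop_idx != -1 and stop_idx * 3 < orig_stop_nt
    novel_aa: int | None = None
    if premature:
        first_altered_codon = offset // 3
        novel_aa = stop_idx - first_altered_codon
    frame_preserving = (len(insert) % 3 == 0) and not premature
    return OrfConsequence(
        frame_preserving=frame_preserving,
        premature_stop=premature,
        novel_aa_before_stop=novel_aa,
    )


# ---------------------------------------------------------------------------
# Cross-species identity

def cross_species_identity(exon_seq: str, target_window: str) -> dict[str, float]:
    """Global pairwise identity between an exon and a cross-species window.

    Needleman–Wunsch with match +1, mismatch −1, gap open −2, gap extend −1;
    percent identity is matches over alignment columns, reported to one
    decimal and as the nearest integer.
    """
    if not exon_seq or not target_window:
        raise ValueError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    alignment = aligner.align(exon_seq.upper(), target_window.upper())[0]
    counts = alignment.counts()
    length = alignment.length
    matches = counts.identities
    pct = 100.0 * matches / length
    return {
        "alignment_length": length,
        "matches": matches,
        "mismatches": counts.mismatches,
        "gaps": counts.gaps,
        "percent_identity": round(pct, 1),
        "percent_identity_int": int(round(pct)),
    }
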