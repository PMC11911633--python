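"""Seeded generators for synthetic muscle-maturation RNA-seq summaries.

The generators emulate the statistical structure the downstream analyses
assume, with fully known planted truth:

* a genome plus reference annotation whose genes exhibit all five AS event
  types as two-isoform genes, with canonical GT-AG introns;
* an "assembled" annotation (the de-novo transcript assembly stand-in)
  that copies the reference and adds isoforms carrying planted novel exons
  inside host introns, on either side of every discovery threshold;
* replicate negative-binomial count matrices over three timepoints
  (E18.5, 2 weeks, 7 weeks; four replicates each) with planted fold
  changes;
* per-base coverage tracks and junction counts realizing planted PSI
  values per group.

Planted novel exons and their host-intron background are written at
constant (noise-free) depth equal to their specified means, so that the
expected filter verdict is well defined even for exons planted exactly at
a threshold; all other coverage is Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    CountMatrix,
    CoverageTrack,
    Gene,
    GeneAnnotation,
    GenomeSequence,
    Interval,
    JunctionCounts,
    Transcript,
    reverse_complement,
)
from .novel_exon import ThresholdConfig
from .splicing import SpliceEvent, classify_events

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOP_CODONS = {"TAA", "TAG", "TGA"}

SPLICE_SITE_STYLES = {
    "canonical": ("GT", "AG"),
    "gc_ag": ("GC", "AG"),
    "at_ac": ("AT", "AC"),
    "noncanonical": ("CA", "TT"),
}


# ---------------------------------------------------------------------------
# Configuration

@dataclass(frozen=True)
class PlantedDE:
    gene: str
    log2fc: float
    stage: str  # "early" (applies from the 2nd timepoint) or "late" (3rd)
    baseline: float | None = None


@dataclass(frozen=True)
class PlantedEvent:
    gene: str
    event_type: str
    psi_per_group: dict[str, float] = field(hash=False)


@dataclass(frozen=True)
class NovelExonSpec:
    """A planted novel exon inside a host gene's intron."""

    host_gene: str
    intron_index: int = 1
    exon_length: int = 62
    mean_coverage: float = 20.0
    background_coverage: float = 0.5
    splice_sites: str = "canonical"
    strand: str = "+"
    in_cds: bool = False  # design the exon to stop translation after 14 aa

    def __post_init__(self) -> None:
        if self.splice_sites not in SPLICE_SITE_STYLES:
            raise ValueError(f"unknown splice-site style {self.splice_sites!r}")
        if self.exon_length < 10:
            raise ValueError("exon_length must be at least 10 nt")

    def expected_trail(self, config: ThresholdConfig) -> list[tuple[str, bool]]:
        ratio = self.mean_coverage / max(self.background_coverage, config.background_floor)
        return [
            ("coverage", self.mean_coverage > config.min_mean_coverage),
            ("background_ratio", ratio >= config.min_background_ratio),
            (
                "canonical_sites",
                SPLICE_SITE_STYLES[self.splice_sites] in config.canonical_pairs,
            ),
        ]

    def expected_verdict(self, config: ThresholdConfig) -> bool:
        return all(ok for _, ok in self.expected_trail(config))


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 1
    n_genes: int = 400
    timepoints: tuple[str, ...] = ("E18.5", "2w", "7w")
    replicates_per_group: int = 4
    read_length: int = 100
    nb_dispersion: float = 0.05
    baseline_log_mean: float = float(np.log(200.0))
    baseline_log_sd: float = 1.0
    junction_depth: float = 100.0
    exon_mean_coverage: float = 30.0
    intron_mean_coverage: float = 0.5
    planted_de: tuple[PlantedDE, ...] = ()
    planted_events: tuple[PlantedEvent, ...] = ()
    planted_novel_exons: tuple[NovelExonSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if len(self.timepoints) < 2:
            raise ValueError("need at least two timepoints")

    def samples(self) -> list[str]:
        return [
            f"{tp}_r{i + 1}"
            for tp in self.timepoints
            for i in range(self.replicates_per_group)
        ]

    def groups(self) -> pd.Series:
        return pd.Series(
            [tp for tp in self.timepoints for _ in range(self.replicates_per_group)],
            index=self.samples(),
            name="group",
        )


def default_config(seed: int = 1) -> SimulationConfig:
    """Study-shaped defaults: three timepoints × four replicates, one gene
    per AS event type with a maturation-like inclusion shift, planted fold
    changes, and novel exons tiling both sides of every discovery filter."""
    events = (
        PlantedEvent("AS_CE", "CE", {"E18.5": 0.2, "2w": 0.8, "7w": 0.85}),
        PlantedEvent("AS_MXE", "MXE", {"E18.5": 0.3, "2w": 0.7, "7w": 0.7}),
        PlantedEvent("AS_A5SS", "A5SS", {"E18.5": 0.8, "2w": 0.35, "7w": 0.3}),
        PlantedEvent("AS_A3SS", "A3SS", {"E18.5": 0.25, "2w": 0.75, "7w": 0.8}),
        PlantedEvent("AS_RI", "RI", {"E18.5": 0.7, "2w": 0.25, "7w": 0.2}),
        PlantedEvent("AS_NULL", "CE", {"E18.5": 0.5, "2w": 0.5, "7w": 0.5}),
    )
    de = tuple(
        PlantedDE(f"DE_E{i:02d}", lfc, "early", baseline=400.0)
        for i, lfc in enumerate([2.0, 2.0, 2.0, -2.0, -2.0, 1.5])
    ) + tuple(
        PlantedDE(f"DE_L{i:02d}", lfc, "late", baseline=400.0)
        for i, lfc in enumerate([2.0, -2.0, 2.5])
    )
    tiers: list[tuple[float, float, str]] = [
        (4.0, 0.2, "canonical"),
        (5.0, 0.2, "canonical"),
        (6.0, 0.2, "canonical"),
        (20.0, 0.2, "canonical"),
        (20.0, 2.5, "canonical"),   # ratio 8
        (20.0, 2.0, "canonical"),   # ratio 10
        (20.0, 20.0 / 12.0, "canonical"),  # ratio 12
        (20.0, 0.5, "gc_ag"),
        (20.0, 0.5, "at_ac"),
        (6.0, 0.75, "canonical"),   # ratio 8
        (4.0, 0.5, "canonical"),    # fails coverage and ratio
        (5.0, 0.5, "canonical"),    # ratio exactly 10, coverage exactly 5
    ]
    novel = tuple(
        NovelExonSpec(
            host_gene=f"NV{i + 1:02d}",
            mean_coverage=cov,
            background_coverage=bg,
            splice_sites=sites,
            strand="+" if i % 2 == 0 else "-",
            exon_length=62 if i % 3 == 0 else 66 + 3 * (i % 4),
        )
        for i, (cov, bg, sites) in enumerate(tiers)
    ) + (
        NovelExonSpec(
            host_gene="NV_ORF",
            mean_coverage=20.0,
            background_coverage=0.5,
            splice_sites="canonical",
            strand="+",
            exon_length=62,
            in_cds=True,
        ),
    )
    return SimulationConfig(
        seed=seed,
        planted_de=de,
        planted_events=events,
        planted_novel_exons=novel,
    )


# ---------------------------------------------------------------------------
# Sequence helpers

def _rand_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _write(seq: np.ndarray, pos: int, nt: str) -> None:
    seq[pos : pos + len(nt)] = np.frombuffer(nt.encode(), dtype="S1")


def random_nonstop_codons(rng: np.random.Generator, n_codons: int) -> str:
    out = []
    while len(out) < n_codons:
        codon = "".join("ACGT"[i] for i in rng.integers(0, 4, 3))
        if codon not in _STOP_CODONS:
            out.append(codon)
    return "".join(out)


def design_stop_insert(
    rng: np.random.Generator, length: int = 62, n_aa: int = 14
) -> str:
    """An insert that, read in frame from its first base, encodes ``n_aa``
    amino acids and then a stop codon."""
    if length < 3 * n_aa + 3:
        raise ValueError("insert too short for requested amino-acid count")
    head = random_nonstop_codons(rng, n_aa)
    tail = "".join("ACGT"[i] for i in rng.integers(0, 4, length - 3 * n_aa - 3))
    return head + "TAA" + tail


def mutate_sequence(seq: str, n_mismatches: int, rng: np.random.Generator) -> str:
    """Substitute ``n_mismatches`` distinct positions with a different base."""
    if n_mismatches > len(seq):
        raise ValueError("more mismatches than positions")
    positions = rng.choice(len(seq), size=n_mismatches, replace=False)
    out = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# Gene structure builders (local 0-based coordinates, genomic order)

_INTRON = 300  # default intron length; large enough for GT..AG placement


def _as_gene_layout(
    event_type: str, strand: str, rng: np.random.Generator
) -> tuple[list[list[tuple[int, int]]], int]:
    """Two-isoform exon layouts realizing one AS event type."""
    L = lambda lo, hi: int(rng.integers(lo, hi))
    if event_type == "CE":
        a, b, c = L(90, 180), L(60, 120), L(90, 180)
        e_a = (0, a)
        e_b = (a + _INTRON, a + _INTRON + b)
        e_c = (e_b[1] + _INTRON, e_b[1] + _INTRON + c)
        return [[e_a, e_b, e_c], [e_a, e_c]], e_c[1]
    if event_type == "MXE":
        a, x1, x2, b = L(90, 180), L(60, 120), L(60, 120), L(90, 180)
        e_a = (0, a)
        e_1 = (a + _INTRON, a + _INTRON + x1)
        e_2 = (e_1[1] + _INTRON, e_1[1] + _INTRON + x2)
        e_b = (e_2[1] + _INTRON, e_2[1] + _INTRON + b)
        return [[e_a, e_1, e_b], [e_a, e_2, e_b]], e_b[1]
    if event_type == "RI":
        a, b = L(90, 180), L(90, 180)
        e_a = (0, a)
        e_b = (a + _INTRON, a + _INTRON + b)
        return [[(0, e_b[1])], [e_a, e_b]], e_b[1]
    if event_type in ("A5SS", "A3SS"):
        # right-variable boundary gives A5SS on '+', A3SS on '-'
        right_variable = (event_type == "A5SS") == (strand == "+")
        ext = L(30, 80)
        if right_variable:
            e = L(90, 180)
            long_x = (0, e + ext)
            short_x = (0, e)
            flank = (long_x[1] + _INTRON, long_x[1] + _INTRON + L(90, 180))
            return [[long_x, flank], [short_x, flank]], flank[1]
        flank = (0, L(90, 180))
        s = flank[1] + _INTRON
        long_x = (s, s + ext + L(90, 180))
        short_x = (s + ext, long_x[1])
        return [[flank, long_x], [flank, short_x]], long_x[1]
    raise ValueError(f"unknown event type {event_type!r}")


def _host_gene_layout(
    spec: NovelExonSpec, rng: np.random.Generator
) -> tuple[list[tuple[int, int]], int, tuple[int, int]]:
    """Four-exon host gene; the spec'd intron is widened to hold the exon."""
    if spec.in_cds:
        exon_lens = [120, 90, 90, 120]
    else:
        exon_lens = [int(rng.integers(90, 200)) for _ in range(4)]
    wide = spec.exon_length + 2 * ThresholdConfig().background_window + 240
    intron_lens = [wide if i == spec.intron_index else _INTRON for i in range(3)]
    exons, pos = [], 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + el))
        pos += el
        if i < 3:
            pos += intron_lens[i]
    intron = (exons[spec.intron_index][1], exons[spec.intron_index + 1][0])
    off = (intron[1] - intron[0] - spec.exon_length) // 2
    novel = (intron[0] + off, intron[0] + off + spec.exon_length)
    return exons, exons[-1][1], novel


# ---------------------------------------------------------------------------
# Genome + annotation generation

def generate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[list[GenomeSequence], GeneAnnotation, GeneAnnotation, dict[str, pd.DataFrame]]:
    """Build the genome, reference and assembled annotations plus truth.

    Returns ``(genomes, reference, assembled, truth)`` where ``truth`` maps
    ``"novel_exons"`` and ``"events"`` to tables listing every planted item.
    Fixing the seed makes all outputs byte-identical.
    """
    rng = np.random.default_rng([config.seed, 101])
    chrom = "chr1"
    gap = 500
    pos = gap
    pieces: list[tuple[int, np.ndarray]] = []
    reference = GeneAnnotation()
    assembled = GeneAnnotation()
    novel_rows: list[dict] = []
    event_rows: list[dict] = []

    def shift(iv: tuple[int, int], off: int) -> tuple[int, int]:
        return (iv[0] + off, iv[1] + off)

    def intron_sites(seq: np.ndarray, s: int, e: int, strand: str) -> None:
        if strand == "+":
            _write(seq, s, "GT")
            _write(seq, e - 2, "AG")
        else:
            _write(seq, s, "CT")
            _write(seq, e - 2, "AC")

    # planted AS genes
    for ev in config.planted_events:
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        layouts, length = _as_gene_layout(ev.event_type, strand, rng)
        seq = _rand_seq(rng, length)
        introns: set[tuple[int, int]] = set()
        for exons in layouts:
            for a, b in zip(exons, exons[1:]):
                introns.add((a[1], b[0]))
        for s, e in introns:
            intron_sites(seq, s, e, strand)
        for k, exons in enumerate(layouts):
            tx = Transcript(
                f"{ev.gene}.t{k + 1}",
                ev.gene,
                [Interval(chrom, *shift(x, pos), strand) for x in exons],
            )
            reference.add_transcript(tx)
            assembled.add_transcript(
                Transcript(f"asm_{tx.id}", f"asm_{ev.gene}", list(tx.exons))
            )
        event_rows.append(
            {
                "gene": ev.gene,
                "event_type": ev.event_type,
                **{f"psi_{g}": p for g, p in ev.psi_per_group.items()},
            }
        )
        pieces.append((pos, seq))
        pos += length + gap

    # novel-exon host genes
    threshold_defaults = ThresholdConfig()
    for spec in config.planted_novel_exons:
        exons, length, novel_local = _host_gene_layout(spec, rng)
        seq = _rand_seq(rng, length)
        cds = None
        if spec.in_cds:
            total = sum(e - s for s, e in exons)
            assert total % 3 == 0
            cds_seq = "ATG" + random_nonstop_codons(rng, total // 3 - 2) + "TAA"
            off = 0
            for s, e in exons:
                _write(seq, s, cds_seq[off : off + (e - s)])
                off += e - s
            cds = exons
            insert = design_stop_insert(rng, spec.exon_length, 14)
            if spec.strand != "+":
                raise ValueError("in_cds host genes are generated on '+'")
            _write(seq, novel_local[0], insert)
        for a, b in zip(exons, exons[1:]):
            intron_sites(seq, a[1], b[0], spec.strand)
        donor, acceptor = SPLICE_SITE_STYLES[spec.splice_sites]
        ns, ne = novel_local
        if spec.strand == "+":
            _write(seq, ns - 2, acceptor)
            _write(seq, ne, donor)
        else:
            _write(seq, ns - 2, reverse_complement(donor))
            _write(seq, ne, reverse_complement(acceptor))
        tx = Transcript(
            f"{spec.host_gene}.t1",
            spec.host_gene,
            [Interval(chrom, *shift(x, pos), spec.strand) for x in exons],
            cds=[Interval(chrom, *shift(x, pos), spec.strand) for x in cds]
            if cds
            else None,
        )
        reference.add_transcript(tx)
        assembled.add_transcript(
            Transcript(f"asm_{tx.id}", f"asm_{spec.host_gene}", list(tx.exons))
        )
        asm_exons = sorted(
            list(tx.exons) + [Interval(chrom, *shift(novel_local, pos), spec.strand)],
            key=lambda e: e.start,
        )
        assembled.add_transcript(
            Transcript(f"STRG_{spec.host_gene}", f"asm_{spec.host_gene}", asm_exons)
        )
        trail = spec.expected_trail(threshold_defaults)
        novel_rows.append(
            {
                "host_gene": spec.host_gene,
                "seq_name": chrom,
                "start": novel_local[0] + pos,
                "end": novel_local[1] + pos,
                "strand": spec.strand,
                "exon_length": spec.exon_length,
                "mean_coverage": spec.mean_coverage,
                "background_coverage": spec.background_coverage,
                "splice_sites": spec.splice_sites,
                "in_cds": spec.in_cds,
                "expected_verdict": spec.expected_verdict(threshold_defaults),
                "expected_fail_filters": ";".join(
                    name for name, ok in trail if not ok
                ),
            }
        )
        pieces.append((pos, seq))
        pos += length + gap

    # filler single/two-isoform genes for panel statistics
    n_filler = max(0, min(30, config.n_genes - len(reference)))
    for i in range(n_filler):
        strand = "+" if i % 2 == 0 else "-"
        n_ex = int(rng.integers(2, 7))
        exons, p = [], 0
        for j in range(n_ex):
            el = int(rng.integers(90, 220))
            exons.append((p, p + el))
            p += el + (_INTRON if j < n_ex - 1 else 0)
        length = exons[-1][1]
        seq = _rand_seq(rng, length)
        for a, b in zip(exons, exons[1:]):
            intron_sites(seq, a[1], b[0], strand)
        gid = f"FG{i + 1:03d}"
        cds = None
        if i % 2 == 0:
            total = sum(e - s for s, e in exons)
            trim = total % 3
            cds = list(exons)
            s_last, e_last = cds[-1]
            if e_last - trim > s_last:
                cds[-1] = (s_last, e_last - trim)
        tx = Transcript(
            f"{gid}.t1",
            gid,
            [Interval(chrom, *shift(x, pos), strand) for x in exons],
            cds=[Interval(chrom, *shift(x, pos), strand) for x in cds] if cds else None,
        )
        reference.add_transcript(tx)
        assembled.add_transcript(Transcript(f"asm_{tx.id}", f"asm_{gid}", list(tx.exons)))
        pieces.append((pos, seq))
        pos += length + gap

    genome_arr = _rand_seq(np.random.default_rng([config.seed, 102]), pos + gap)
    for off, seq in pieces:
        genome_arr[off : off + len(seq)] = seq
    genome = GenomeSequence(chrom, genome_arr.tobytes().decode())
    truth = {
        "novel_exons": pd.DataFrame(novel_rows),
        "events": pd.DataFrame(event_rows),
    }
    return [genome], reference, assembled, truth


# ---------------------------------------------------------------------------
# Counts

def simulate_counts(
    config: SimulationConfig, gene_ids: Sequence[str] | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB counts per gene × sample with planted fold changes.

    Counts follow NegativeBinomial(mean = baseline × 2^(log2FC × stage
    indicator) × size factor, dispersion = ``nb_dispersion``); size factors
    are log-uniform in [0.7, 1.4].  Returns the matrix and the DE truth.
    """
    rng = np.random.default_rng([config.seed, 201])
    planted = {p.gene: p for p in config.planted_de}
    if gene_ids is None:
        n_named = len(planted)
        filler = [f"G{i + 1:04d}" for i in range(max(0, config.n_genes - n_named))]
        gene_ids = list(planted) + filler
    else:
        gene_ids = list(gene_ids)
        missing = set(planted) - set(gene_ids)
        gene_ids += sorted(missing)

    samples = config.samples()
    groups = config.groups()
    size = np.exp(rng.uniform(np.log(0.7), np.log(1.4), len(samples)))
    baselines = np.exp(
        rng.normal(config.baseline_log_mean, config.baseline_log_sd, len(gene_ids))
    )
    tp_index = {tp: i for i, tp in enumerate(config.timepoints)}

    mat = np.zeros((len(gene_ids), len(samples)), dtype=int)
    for gi, gene in enumerate(gene_ids):
        base = baselines[gi]
        p = planted.get(gene)
        if p is not None and p.baseline is not None:
            base = p.baseline
        mult = np.ones(len(config.timepoints))
        if p is not None:
            start = 1 if p.stage == "early" else 2
            mult[start:] *= 2.0**p.log2fc
        for sj, sample in enumerate(samples):
            mu = base * mult[tp_index[groups[sample]]] * size[sj]
            if config.nb_dispersion <= 1e-12:
                mat[gi, sj] = rng.poisson(mu)
            else:
                n = 1.0 / config.nb_dispersion
                mat[gi, sj] = rng.negative_binomial(n, n / (n + mu))
    counts = CountMatrix(
        pd.DataFrame(mat, index=gene_ids, columns=samples), groups
    )
    truth = pd.DataFrame(
        [
            {"gene": p.gene, "stage": p.stage, "log2fc": p.log2fc}
            for p in config.planted_de
        ]
    )
    return counts, truth


# ---------------------------------------------------------------------------
# Coverage and junctions

def _planted_event_objects(
    config: SimulationConfig, reference: GeneAnnotation
) -> dict[str, SpliceEvent]:
    """Match each planted event to the classified event of its gene."""
    out: dict[str, SpliceEvent] = {}
    for p in config.planted_events:
        gene = reference.genes[p.gene]
        matches = [e for e in classify_events(gene) if e.event_type == p.event_type]
        if len(matches) != 1:
            raise ValueError(
                f"gene {p.gene} yields {len(matches)} {p.event_type} events; "
                "expected exactly one"
            )
        out[p.gene] = matches[0]
    return out


def simulate_junctions_for_events(
    events: list[SpliceEvent],
    psi_per_group: list[dict[str, float]],
    groups: pd.Series,
    depth: float,
    rng: np.random.Generator,
) -> JunctionCounts:
    """Poisson junction counts realizing a target PSI per group per event.

    Each inclusion junction draws Poisson(depth × ψ) and each skipping
    junction Poisson(depth × (1 − ψ)), so the junction-count PSI estimator
    converges to ψ as depth grows.
    """
    jc = JunctionCounts()
    for ev, psis in zip(events, psi_per_group):
        for sample in groups.index:
            psi = psis[groups[sample]]
            if not 0.0 <= psi <= 1.0:
                raise ValueError(f"PSI {psi} outside [0,1]")
            for key in ev.inclusion_junctions:
                jc.add(key, sample, int(rng.poisson(depth * psi)))
            for key in ev.skipping_junctions:
                jc.add(key, sample, int(rng.poisson(depth * (1.0 - psi))))
    return jc


def simulate_coverage_and_junctions(
    config: SimulationConfig,
    reference: GeneAnnotation,
    truth_novel: pd.DataFrame,
) -> tuple[dict[str, CoverageTrack], JunctionCounts]:
    """Per-sample coverage tracks plus junction counts for planted events.

    Exonic depth is Poisson around the constitutive exon mean; planted
    novel exons and their host introns are written at their exact specified
    depths; other intronic positions are Poisson around the intron mean.
    Constitutive (non-event) transcript junctions receive Poisson counts at
    the nominal junction depth.
    """
    rng = np.random.default_rng([config.seed, 301])
    groups = config.groups()
    lengths: dict[str, int] = {}
    for gene in reference:
        iv = gene.interval
        lengths[iv.seq_name] = max(lengths.get(iv.seq_name, 0), iv.end + 1000)

    planted_hosts = (
        {r.host_gene: r for r in truth_novel.itertuples(index=False)}
        if len(truth_novel)
        else {}
    )
    tracks: dict[str, CoverageTrack] = {}
    for sample in groups.index:
        arrays = {name: np.zeros(n) for name, n in lengths.items()}
        for gene in reference:
            arr = arrays[gene.seq_name]
            for block in gene.exon_union():
                arr[block.start : block.end] = rng.poisson(
                    config.exon_mean_coverage, len(block)
                )
            for intron in gene.intron_union():
                arr[intron.start : intron.end] = rng.poisson(
                    config.intron_mean_coverage, len(intron)
                )
            row = planted_hosts.get(gene.gene_id)
            if row is not None:
                intron = next(
                    i
                    for i in gene.intron_union()
                    if i.start <= row.start and row.end <= i.end
                )
                arr[intron.start : intron.end] = row.background_coverage
                arr[row.start : row.end] = row.mean_coverage
        tracks[sample] = CoverageTrack(arrays)

    ev_by_gene = _planted_event_objects(config, reference)
    events = [ev_by_gene[p.gene] for p in config.planted_events]
    psis = [p.psi_per_group for p in config.planted_events]
    junctions = simulate_junctions_for_events(
        events, psis, groups, config.junction_depth, rng
    )
    event_keys = {
        k for ev in events for k in ev.inclusion_junctions + ev.skipping_junctions
    }
    for tx in reference.transcripts():
        for intron in tx.introns():
            key = (intron.seq_name, intron.start, intron.end, intron.strand)
            if key in event_keys:
                continue
            for sample in groups.index:
                junctions.add(key, sample, int(rng.poisson(config.junction_depth)))
    return tracks, junctions


def pooled_coverage(tracks: dict[str, CoverageTrack]) -> CoverageTrack:
    """Base-wise mean depth across samples."""
    names = next(iter(tracks.values())).depths.keys()
    return CoverageTrack(
        {
            name: np.mean([t.depths[name] for t in tracks.values()], axis=0)
            for name in names
        }
    )


# ---------------------------------------------------------------------------
# One-call orchestration

@dataclass
class SimulationResult:
    config: SimulationConfig
    genomes: list[GenomeSequence]
    reference: GeneAnnotation
    assembled: GeneAnnotation
    counts: CountMatrix
    coverage: dict[str, CoverageTrack]
    junctions: JunctionCounts
    truth: dict[str, pd.DataFrame]

    @property
    def pooled_coverage(self) -> CoverageTrack:
        return pooled_coverage(self.coverage)


def simulate_all(config: SimulationConfig) -> SimulationResult:
    """Generate every input the pipeline consumes, with planted truth."""
    genomes, reference, assembled, truth = generate_genome_and_annotation(config)
    gene_ids = list(reference.genes)
    counts, truth_de = simulate_counts(config, gene_ids=gene_ids)
    truth["de"] = truth_de
    coverage, junctions = simulate_coverage_and_junctions(
        config, reference, truth["novel_exons"]
    )
    return SimulationResult(
        config, genomes, reference, assembled, counts, coverage, junctions, truth
    )
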