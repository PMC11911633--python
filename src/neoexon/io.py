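"""Readers and writers for the standard formats the pipeline consumes.

Conventions at the file boundary:

* FASTA — multi-record, sequences uppercased on read.
* GTF — 1-based inclusive coordinates (Ensembl attribute dialect), converted
  to the internal 0-based half-open convention on read and back on write.
* bedGraph — 0-based half-open; overlapping intervals are rejected.
* junction TSV — header ``seq  intron_start  intron_end  strand  sample
  count`` with the intron given 0-based half-open.
* GMT — tab-separated gene sets: name, description, member genes.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

from .core import (
    BoundsError,
    CountMatrix,
    CoverageTrack,
    FormatError,
    GeneAnnotation,
    GenomeSequence,
    Interval,
    JunctionCounts,
    Transcript,
)

log = logging.getLogger(__name__)

JUNCTION_COLUMNS = ["seq", "intron_start", "intron_end", "strand", "sample", "count"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    path = Path(path)
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: record with empty header")
            if len(rec.seq) == 0:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            records.append(GenomeSequence(rec.id, str(rec.seq)))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    return records


def write_fasta(sequences: Iterable[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.name}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path: str | Path, dialect: str = "ensembl") -> GeneAnnotation:
    """Parse exon and CDS features of a GTF into a :class:`GeneAnnotation`.

    ``dialect`` is accepted for provenance ('ensembl' or 'stringtie'); both
    use the same ``key "value";`` attribute syntax.
    """
    if dialect not in ("ensembl", "stringtie"):
        raise ValueError(f"unknown GTF dialect {dialect!r}")
    path = Path(path)
    exons: dict[tuple[str, str], list[Interval]] = {}
    cds: dict[tuple[str, str], list[Interval]] = {}
    biotypes: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed line
                raise FormatError(f"{path}:{lineno}: unparseable GTF line ({exc})")
            if feat.featuretype not in ("exon", "CDS"):
                continue
            attrs = feat.attributes
            if "gene_id" not in attrs or not attrs["gene_id"]:
                raise FormatError(f"{path}:{lineno}: feature without gene_id")
            if "transcript_id" not in attrs or not attrs["transcript_id"]:
                raise FormatError(f"{path}:{lineno}: feature without transcript_id")
            gid = attrs["gene_id"][0]
            tid = attrs["transcript_id"][0]
            if "gene_biotype" in attrs:
                biotypes[gid] = attrs["gene_biotype"][0]
            # GTF is 1-based inclusive; internal is 0-based half-open
            iv = Interval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            target = exons if feat.featuretype == "exon" else cds
            target.setdefault((gid, tid), []).append(iv)

    annotation = GeneAnnotation()
    for (gid, tid), ivs in exons.items():
        try:
            tx = Transcript(tid, gid, ivs, cds.get((gid, tid)))
        except ValueError as exc:
            raise FormatError(f"{path}: transcript {tid}: {exc}")
        annotation.add_transcript(tx, biotype=biotypes.get(gid, "protein_coding"))
    for (gid, tid) in cds:
        if (gid, tid) not in exons:
            raise FormatError(f"{path}: CDS for {tid} without exon features")
    return annotation


def write_gtf(annotation: GeneAnnotation, path: str | Path, source: str = "neoexon") -> None:
    with open(path, "w") as fh:
        for gene in sorted(annotation, key=lambda g: (g.seq_name, g.interval.start)):
            for tid in sorted(gene.transcripts):
                tx = gene.transcripts[tid]
                attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.id}"; gene_biotype "{gene.biotype}";'
                for ftype, ivs in (("exon", tx.exons), ("CDS", tx.cds or [])):
                    for iv in ivs:
                        fh.write(
                            "\t".join(
                                [
                                    iv.seq_name,
                                    source,
                                    ftype,
                                    str(iv.start + 1),
                                    str(iv.end),
                                    ".",
                                    iv.strand,
                                    ".",
                                    attrs,
                                ]
                            )
                            + "\n"
                        )


# ---------------------------------------------------------------------------
# bedGraph coverage

def read_coverage_bedgraph(
    path: str | Path, sequences: Iterable[GenomeSequence]
) -> CoverageTrack:
    """Dense per-base track from a bedGraph; unlisted positions are 0.

    Overlapping intervals are a format error: the simulator always writes
    disjoint blocks, so an overlap signals a malformed file.
    """
    path = Path(path)
    lengths = {s.name: len(s) for s in sequences}
    arrays = {name: np.zeros(n) for name, n in lengths.items()}
    covered = {name: np.zeros(n, dtype=bool) for name, n in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            name, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if name not in arrays:
                raise FormatError(f"{path}:{lineno}: unknown sequence {name!r}")
            if not 0 <= s < e:
                raise FormatError(f"{path}:{lineno}: invalid interval [{s},{e})")
            if e > lengths[name]:
                raise BoundsError(
                    f"{path}:{lineno}: interval end {e} exceeds {name} length {lengths[name]}"
                )
            if v < 0:
                raise FormatError(f"{path}:{lineno}: negative depth {v}")
            if covered[name][s:e].any():
                raise FormatError(f"{path}:{lineno}: overlapping bedGraph intervals")
            arrays[name][s:e] = v
            covered[name][s:e] = True
    return CoverageTrack(arrays)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as disjoint constant-depth blocks, zeros omitted."""
    with open(path, "w") as fh:
        for name in sorted(track.depths):
            arr = track.depths[name]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{name}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# Junction TSV

def read_junctions(path: str | Path) -> JunctionCounts:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(JUNCTION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing junction columns {sorted(missing)}")
    jc = JunctionCounts()
    for row in df.itertuples(index=False):
        jc.add(
            (str(row.seq), int(row.intron_start), int(row.intron_end), str(row.strand)),
            str(row.sample),
            int(row.count),
        )
    return jc


def write_junctions(junctions: JunctionCounts, path: str | Path) -> None:
    rows = []
    for key in junctions.keys():
        seq, s, e, strand = key
        for sample in junctions.samples():
            c = junctions.get(key, sample)
            if c:
                rows.append((seq, s, e, strand, sample, c))
    pd.DataFrame(rows, columns=JUNCTION_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Count matrix TSV

def read_counts(counts_path: str | Path, groups_path: str | Path) -> CountMatrix:
    """Counts TSV (gene_id index) plus a two-column sample→group TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t")
    if groups_df.shape[1] < 2:
        raise FormatError(f"{groups_path}: expected columns sample, group")
    groups = pd.Series(
        groups_df.iloc[:, 1].values, index=groups_df.iloc[:, 0].astype(str)
    )
    counts.columns = counts.columns.astype(str)
    missing = set(counts.columns) - set(groups.index)
    if missing:
        raise FormatError(f"{groups_path}: no group for samples {sorted(missing)}")
    return CountMatrix(counts, groups.loc[list(counts.columns)])


def write_counts(matrix: CountMatrix, counts_path: str | Path, groups_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    pd.DataFrame(
        {"sample": matrix.groups.index, "group": matrix.groups.values}
    ).to_csv(groups_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and ≥1 gene"
                )
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
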