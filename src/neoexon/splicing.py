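"""Alternative-splicing event classification and PSI quantification.

Events are defined from annotated transcript structures by pairwise isoform
comparison, in the five-type taxonomy used for short-read splicing analysis:
cassette exon (CE), mutually exclusive exons (MXE), alternative 5'/3' splice
site (A5SS/A3SS, named on the transcribed strand) and retained intron (RI).

PSI (percent spliced in) is estimated from junction read counts only,

    PSI = (I / n_inc) / (I / n_inc + S / n_skip),

where I and S are summed inclusion and skipping reads and n_inc, n_skip the
number of distinct inclusion/skipping junctions (CE 2:1, MXE 2:2, A5SS/A3SS
1:1, RI 2:1 with the two exon–intron boundaries acting as inclusion
junctions).  Differential inclusion between two groups uses a Welch t-test
on logit-PSI and calls events significant at the strict thresholds
FDR < 0.01 and |ΔPSI| > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd
from scipy import stats

from .core import Gene, GeneAnnotation, Interval, JunctionCounts, JunctionKey
from .diffexpr import bh_adjust

EVENT_TYPES = ("CE", "MXE", "A5SS", "A3SS", "RI")

FDR_THRESHOLD = 0.01
DPSI_THRESHOLD = 0.05
PSI_CLAMP = 0.01


@dataclass
class SpliceEvent:
    """A typed AS event with its defining intervals and junction keys."""

    event_id: str
    gene_id: str
    event_type: str
    intervals: dict[str, Interval]
    inclusion_junctions: list[JunctionKey]
    skipping_junctions: list[JunctionKey]
    psi: dict[str, float] = field(default_factory=dict)
    delta_psi: float = float("nan")
    p: float = float("nan")
    fdr: float = float("nan")
    significant: bool = False
    testable: bool = True

    def key(self) -> tuple:
        coords = tuple(
            (role, iv.seq_name, iv.start, iv.end)
            for role, iv in sorted(self.intervals.items())
        )
        return (self.gene_id, self.event_type, coords)


def _exon_tuples(tx) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in tx.exons]


def _iv(gene: Gene, start: int, end: int) -> Interval:
    return Interval(gene.seq_name, start, end, gene.strand)


def _pair_events(gene: Gene, tx1, tx2) -> list[SpliceEvent]:
    """All events distinguishing one ordered transcript pair."""
    seq, strand = gene.seq_name, gene.strand
    e1, e2 = _exon_tuples(tx1), _exon_tuples(tx2)
    s1, s2 = set(e1), set(e2)
    events: list[SpliceEvent] = []

    def jk(a: int, b: int) -> JunctionKey:
        return (seq, a, b, strand)

    def add(ev_type: str, intervals: dict[str, Interval], inc, skip) -> None:
        events.append(
            SpliceEvent(
                event_id="",
                gene_id=gene.gene_id,
                event_type=ev_type,
                intervals=intervals,
                inclusion_junctions=inc,
                skipping_junctions=skip,
            )
        )

    # --- cassette exons: internal exon of one isoform absent from the other,
    # whose neighbours are shared and directly spliced together there
    for a, b, only_a, other in ((e1, e2, s1 - s2, s2), (e2, e1, s2 - s1, s1)):
        for i in range(1, len(a) - 1):
            ex = a[i]
            if ex not in only_a:
                continue
            prev, nxt = a[i - 1], a[i + 1]
            if prev in other and nxt in other:
                j = b.index(prev)
                if j + 1 < len(b) and b[j + 1] == nxt:
                    add(
                        "CE",
                        {
                            "cassette": _iv(gene, *ex),
                            "upstream": _iv(gene, *prev),
                            "downstream": _iv(gene, *nxt),
                        },
                        [jk(prev[1], ex[0]), jk(ex[1], nxt[0])],
                        [jk(prev[1], nxt[0])],
                    )

    # --- mutually exclusive exons: each isoform holds one of two
    # non-overlapping internal exons between the same shared flanks
    for i in range(1, len(e1) - 1):
        x1 = e1[i]
        if x1 in s2:
            continue
        prev, nxt = e1[i - 1], e1[i + 1]
        if prev not in s2 or nxt not in s2:
            continue
        for j in range(1, len(e2) - 1):
            x2 = e2[j]
            if x2 in s1 or x2 == x1:
                continue
            if e2[j - 1] != prev or e2[j + 1] != nxt:
                continue
            if x1[1] <= x2[0] or x2[1] <= x1[0]:  # non-overlapping
                first, second = sorted((x1, x2))
                add(
                    "MXE",
                    {
                        "exon1": _iv(gene, *first),
                        "exon2": _iv(gene, *second),
                        "upstream": _iv(gene, *prev),
                        "downstream": _iv(gene, *nxt),
                    },
                    [jk(prev[1], first[0]), jk(first[1], nxt[0])],
                    [jk(prev[1], second[0]), jk(second[1], nxt[0])],
                )

    # --- alternative donor/acceptor: two exons sharing exactly one boundary,
    # spliced to the same neighbour across the variable junction
    for i, xa in enumerate(e1):
        for j, xb in enumerate(e2):
            if xa == xb:
                continue
            if xa[0] == xb[0] and xa[1] != xb[1]:
                # variable right (genomic downstream) boundary
                if i + 1 >= len(e1) or j + 1 >= len(e2):
                    continue
                if e1[i + 1] != e2[j + 1]:
                    continue
                flank = e1[i + 1]
                long_x, short_x = (xa, xb) if xa[1] > xb[1] else (xb, xa)
                ev_type = "A5SS" if strand == "+" else "A3SS"
                add(
                    ev_type,
                    {
                        "long": _iv(gene, *long_x),
                        "short": _iv(gene, *short_x),
                        "flank": _iv(gene, *flank),
                    },
                    [jk(long_x[1], flank[0])],
                    [jk(short_x[1], flank[0])],
                )
            elif xa[1] == xb[1] and xa[0] != xb[0]:
                # variable left (genomic upstream) boundary
                if i == 0 or j == 0:
                    continue
                if e1[i - 1] != e2[j - 1]:
                    continue
                flank = e1[i - 1]
                long_x, short_x = (xa, xb) if xa[0] < xb[0] else (xb, xa)
                ev_type = "A3SS" if strand == "+" else "A5SS"
                add(
                    ev_type,
                    {
                        "long": _iv(gene, *long_x),
                        "short": _iv(gene, *short_x),
                        "flank": _iv(gene, *flank),
                    },
                    [jk(flank[1], long_x[0])],
                    [jk(flank[1], short_x[0])],
                )

    # --- retained introns: one isoform's exon spans an exon-intron-exon
    # block of the other with matching outer boundaries
    for a, b in ((e1, e2), (e2, e1)):
        for ex in a:
            for j in range(len(b) - 1):
                x, y = b[j], b[j + 1]
                if ex[0] == x[0] and ex[1] == y[1] and y[0] - x[1] >= 2:
                    add(
                        "RI",
                        {
                            "retained": _iv(gene, *ex),
                            "intron": _iv(gene, x[1], y[0]),
                            "exon5": _iv(gene, *x),
                            "exon3": _iv(gene, *y),
                        },
                        [jk(x[1], x[1] + 1), jk(y[0] - 1, y[0])],
                        [jk(x[1], y[0])],
                    )
    return events


def classify_events(gene: Gene) -> list[SpliceEvent]:
    """AS events of a gene from all pairwise isoform comparisons.

    Events found in more than one transcript pair are reported once,
    deduplicated by type and defining coordinates.  A single-isoform gene
    yields no events.
    """
    txs = list(gene.transcripts.values())
    seen: dict[tuple, SpliceEvent] = {}
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            for ev in _pair_events(gene, txs[i], txs[j]):
                seen.setdefault(ev.key(), ev)
    events = sorted(
        seen.values(),
        key=lambda e: (e.event_type, min(iv.start for iv in e.intervals.values())),
    )
    for k, ev in enumerate(events):
        anchor = min(ev.intervals.values(), key=lambda iv: iv.start)
        ev.event_id = f"{gene.gene_id}:{ev.event_type}:{anchor.start}-{anchor.end}:{k}"
    return events


def classify_annotation(annotation: GeneAnnotation) -> list[SpliceEvent]:
    out: list[SpliceEvent] = []
    for gene in annotation:
        out.extend(classify_events(gene))
    return out


def compute_psi(
    event: SpliceEvent, junctions: JunctionCounts, sample: str
) -> float | None:
    """Junction-based PSI for one sample; None when no informative reads."""
    inc = sum(junctions.get(k, sample) for k in event.inclusion_junctions)
    skip = sum(junctions.get(k, sample) for k in event.skipping_junctions)
    if inc + skip == 0:
        return None
    ni = len(event.inclusion_junctions)
    ns = len(event.skipping_junctions)
    inc_rate = inc / ni
    skip_rate = skip / ns
    return inc_rate / (inc_rate + skip_rate)


def _logit(p: np.ndarray) -> np.ndarray:
    q = np.clip(p, PSI_CLAMP, 1 - PSI_CLAMP)
    return np.log(q / (1 - q))


class DifferentialInclusion:
    """Two-group differential-inclusion model over a set of AS events.

    Replicate PSI values are computed from junction counts; the group
    difference is tested per event by a Welch t-test on logit-PSI and
    adjusted by Benjamini–Hochberg across testable events.
    """

    def __init__(
        self,
        events: list[SpliceEvent],
        junctions: JunctionCounts,
        groups: pd.Series,
        group_a: str,
        group_b: str,
    ) -> None:
        self.events = events
        self.junctions = junctions
        self.groups = groups
        self.group_a = group_a
        self.group_b = group_b

    def fit(self) -> pd.DataFrame:
        samples_a = [s for s in self.groups.index if self.groups[s] == self.group_a]
        samples_b = [s for s in self.groups.index if self.groups[s] == self.group_b]
        raw_p: list[float] = []
        testable_idx: list[int] = []
        for i, ev in enumerate(self.events):
            for s in samples_a + samples_b:
                val = compute_psi(ev, self.junctions, s)
                if val is not None:
                    ev.psi[s] = val
            a = np.array([ev.psi[s] for s in samples_a if s in ev.psi])
            b = np.array([ev.psi[s] for s in samples_b if s in ev.psi])
            if len(a) < 2 or len(b) < 2:
                ev.testable = False
                ev.significant = False
                continue
            ev.delta_psi = float(b.mean() - a.mean())
            la, lb = _logit(a), _logit(b)
            if la.var(ddof=1) == 0 and lb.var(ddof=1) == 0:
                p = 1.0 if la.mean() == lb.mean() else 0.0
            else:
                p = float(stats.ttest_ind(la, lb, equal_var=False).pvalue)
            ev.p = p
            raw_p.append(p)
            testable_idx.append(i)
        if raw_p:
            adj = bh_adjust(raw_p)
            for idx, q in zip(testable_idx, adj):
                ev = self.events[idx]
                ev.fdr = float(q)
                ev.significant = bool(
                    ev.fdr < FDR_THRESHOLD and abs(ev.delta_psi) > DPSI_THRESHOLD
                )
        return events_frame(self.events)


def differential_inclusion(
    events: list[SpliceEvent],
    junctions: JunctionCounts,
    groups: pd.Series,
    group_a: str,
    group_b: str,
) -> list[SpliceEvent]:
    """Functional wrapper around :class:`DifferentialInclusion`."""
    DifferentialInclusion(events, junctions, groups, group_a, group_b).fit()
    return events


def events_frame(events: list[SpliceEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        row = {
            "event_id": ev.event_id,
            "gene_id": ev.gene_id,
            "event_type": ev.event_type,
            "delta_psi": ev.delta_psi,
            "p": ev.p,
            "fdr": ev.fdr,
            "significant": ev.significant,
            "testable": ev.testable,
        }
        for role, iv in ev.intervals.items():
            row[f"{role}_coords"] = f"{iv.seq_name}:{iv.start}-{iv.end}"
        for s, v in ev.psi.items():
            row[f"psi_{s}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def event_repartition(
    events: list[SpliceEvent],
    panel: set[str],
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Significant-event counts and affected-gene percentages by type.

    A gene counts as affected by a type if it has at least one significant
    event of that type; the percentage divides by the number of genes in the
    panel (resp. non-panel background of ``universe``).  Event counts tally
    every significant event, so a gene with three cassette events adds three
    to the count but one to the percentage.
    """
    if universe is None:
        universe = {ev.gene_id for ev in events}
    background = universe - panel
    sig = [ev for ev in events if ev.significant]
    rows = []
    for ev_type in EVENT_TYPES:
        of_type = [ev for ev in sig if ev.event_type == ev_type]
        row: dict[str, object] = {"event_type": ev_type}
        for name, gene_set in (("panel", panel), ("background", background)):
            in_set = [ev for ev in of_type if ev.gene_id in gene_set]
            genes_hit = {ev.gene_id for ev in in_set}
            row[f"{name}_events"] = len(in_set)
            row[f"{name}_pct_genes"] = (
                100.0 * len(genes_hit) / len(gene_set) if gene_set else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("event_type")
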