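import numpy as np
import pandas as pd
import pytest

from neoexon.core import Gene, GeneAnnotation, Interval, JunctionCounts
from neoexon.splicing import (
    SpliceEvent,
    classify_events,
    compute_psi,
    differential_inclusion,
    event_repartition,
)

from conftest import make_transcript
from oracles import classify_pair


def build_gene(gene_id, isoforms, strand="+"):
    ann = GeneAnnotation()
    for k, exons in enumerate(isoforms):
        ann.add_transcript(make_transcript(f"{gene_id}.t{k}", gene_id, exons, strand))
    return ann.genes[gene_id]


def signature(ev):
    """Map a classified event onto the oracle's signature space."""
    iv = {k: (v.start, v.end) for k, v in ev.intervals.items()}
    if ev.event_type == "CE":
        return ("CE", iv["cassette"])
    if ev.event_type == "MXE":
        return ("MXE", tuple(sorted((iv["exon1"], iv["exon2"]))))
    if ev.event_type in ("A5SS", "A3SS"):
        long_x, short_x = iv["long"], iv["short"]
        if long_x[0] == short_x[0]:
            sig = (long_x[0], tuple(sorted((long_x[1], short_x[1]))))
        else:
            sig = (long_x[1], tuple(sorted((long_x[0], short_x[0]))))
        return (ev.event_type, sig)
    if ev.event_type == "RI":
        return ("RI", (iv["intron"][0], iv["intron"][1]))
    raise AssertionError(ev.event_type)


def random_two_isoform_gene(rng, strand):
    """A base transcript plus one structural modification with known type."""
    n = int(rng.integers(3, 8))
    exons, pos = [], 0
    for _ in range(n):
        length = int(rng.integers(50, 150))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(120, 300))
    op = rng.choice(["CE", "MXE", "ALT", "RI"])
    iso2 = list(exons)
    if op == "CE":
        k = int(rng.integers(1, n - 1))
        iso2.pop(k)
    elif op == "MXE":
        k = int(rng.integers(1, n - 1))
        s, e = exons[k]
        gap_end = exons[k + 1][0]
        new_len = min(40, gap_end - e - 20)
        if new_len < 10:
            return random_two_isoform_gene(rng, strand)
        iso2[k] = (e + 10, e + 10 + new_len)
    elif op == "ALT":
        k = int(rng.integers(1, n - 1))
        s, e = exons[k]
        side = rng.choice(["start", "end"])
        shift = int(rng.integers(5, 30))
        iso2[k] = (s + shift, e) if side == "start" else (s, e - shift)
    else:  # RI
        k = int(rng.integers(0, n - 1))
        iso2 = exons[:k] + [(exons[k][0], exons[k + 1][1])] + exons[k + 2 :]
    return build_gene("g", [exons, iso2], strand)


class TestClassification:
    def test_single_cassette_exon(self, two_isoform_gene):
        events = classify_events(two_isoform_gene)
        assert [e.event_type for e in events] == ["CE"]
        ce = events[0]
        assert (ce.intervals["cassette"].start, ce.intervals["cassette"].end) == (200, 260)
        assert len(ce.inclusion_junctions) == 2
        assert len(ce.skipping_junctions) == 1

    def test_minus_strand_alternative_donor_is_a5ss(self):
        # on '-', the donor side is the genomic *left* boundary of the
        # downstream intron; a variable left boundary with a shared
        # left-adjacent exon is therefore an alternative 5' splice site
        gene = build_gene(
            "g", [[(0, 100), (300, 400)], [(0, 100), (330, 400)]], strand="-"
        )
        events = classify_events(gene)
        assert [e.event_type for e in events] == ["A5SS"]

    def test_plus_strand_same_topology_is_a3ss(self):
        gene = build_gene(
            "g", [[(0, 100), (300, 400)], [(0, 100), (330, 400)]], strand="+"
        )
        assert [e.event_type for e in classify_events(gene)] == ["A3SS"]

    def test_duplicate_event_across_pairs_deduplicated(self):
        gene = build_gene(
            "g",
            [
                [(0, 100), (200, 260), (400, 500)],
                [(0, 100), (400, 500)],
                [(0, 100), (400, 500), (600, 700)],
            ],
        )
        ce = [e for e in classify_events(gene) if e.event_type == "CE"]
        assert len(ce) == 1

    def test_single_transcript_gene_has_no_events(self):
        gene = build_gene("g", [[(0, 100), (200, 300)]])
        assert classify_events(gene) == []

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_exon_set_difference_oracle(self, strand):
        rng = np.random.default_rng(2024 if strand == "+" else 2025)
        for _ in range(200):
            gene = random_two_isoform_gene(rng, strand)
            t1, t2 = list(gene.transcripts.values())
            expected = classify_pair(
                [(e.start, e.end) for e in t1.exons],
                [(e.start, e.end) for e in t2.exons],
                strand,
            )
            got = {signature(ev) for ev in classify_events(gene)}
            assert got == expected

    def test_strand_flip_swaps_a5ss_a3ss_only(self):
        rng = np.random.default_rng(77)
        swap = {"A5SS": "A3SS", "A3SS": "A5SS", "CE": "CE", "MXE": "MXE", "RI": "RI"}
        for _ in range(50):
            gene_plus = random_two_isoform_gene(rng, "+")
            isoforms = [
                [(e.start, e.end) for e in t.exons]
                for t in gene_plus.transcripts.values()
            ]
            gene_minus = build_gene("g", isoforms, strand="-")
            types_plus = sorted(e.event_type for e in classify_events(gene_plus))
            types_minus = sorted(e.event_type for e in classify_events(gene_minus))
            assert sorted(swap[t] for t in types_plus) == types_minus


def ce_event():
    return SpliceEvent(
        "e1", "g", "CE", {},
        inclusion_junctions=[("c", 100, 200, "+"), ("c", 260, 400, "+")],
        skipping_junctions=[("c", 100, 400, "+")],
    )


class TestPsi:
    def test_no_inclusion_reads_gives_zero(self):
        jc = JunctionCounts()
        jc.add(("c", 100, 400, "+"), "s1", 30)
        assert compute_psi(ce_event(), jc, "s1") == 0.0

    def test_hand_evaluated_ce_formula(self):
        jc = JunctionCounts()
        jc.add(("c", 100, 200, "+"), "s1", 10)
        jc.add(("c", 260, 400, "+"), "s1", 10)
        jc.add(("c", 100, 400, "+"), "s1", 10)
        # (20/2) / (20/2 + 10/1) = 0.5
        assert compute_psi(ce_event(), jc, "s1") == pytest.approx(0.5)

    def test_missing_when_uninformative(self):
        assert compute_psi(ce_event(), JunctionCounts(), "s1") is None

    def test_invariant_under_uniform_count_scaling(self):
        jc1, jc2 = JunctionCounts(), JunctionCounts()
        for key, c in [
            (("c", 100, 200, "+"), 7),
            (("c", 260, 400, "+"), 13),
            (("c", 100, 400, "+"), 5),
        ]:
            jc1.add(key, "s1", c)
            jc2.add(key, "s1", 10 * c)
        assert compute_psi(ce_event(), jc1, "s1") == pytest.approx(
            compute_psi(ce_event(), jc2, "s1")
        )


def exact_psi_junctions(psi_by_sample):
    """CE junction counts realizing each sample's PSI exactly."""
    jc = JunctionCounts()
    ev = ce_event()
    for sample, psi in psi_by_sample.items():
        inc = int(round(100 * psi))
        skip = int(round(100 * (1 - psi)))
        for key in ev.inclusion_junctions:
            jc.add(key, sample, inc)
        for key in ev.skipping_junctions:
            jc.add(key, sample, skip)
    return ev, jc


class TestDifferentialInclusion:
    def groups(self):
        return pd.Series(
            ["A"] * 4 + ["B"] * 4,
            index=[f"A{i}" for i in range(4)] + [f"B{i}" for i in range(4)],
        )

    def test_identical_psi_not_significant(self):
        ev, jc = exact_psi_junctions(
            {s: 0.5 for s in self.groups().index}
        )
        differential_inclusion([ev], jc, self.groups(), "A", "B")
        assert ev.delta_psi == 0.0
        assert not ev.significant

    def test_delta_exactly_at_threshold_not_significant(self):
        psi = {f"A{i}": 0.40 for i in range(4)} | {f"B{i}": 0.45 for i in range(4)}
        ev, jc = exact_psi_junctions(psi)
        differential_inclusion([ev], jc, self.groups(), "A", "B")
        assert ev.delta_psi == pytest.approx(0.05)
        assert ev.fdr < 0.01  # zero within-group variance
        assert not ev.significant  # strict |dPSI| > 0.05

    def test_large_separation_is_significant(self):
        rng = np.random.default_rng(8)
        from neoexon.simulate import simulate_junctions_for_events

        ev = ce_event()
        jc = simulate_junctions_for_events(
            [ev], [{"A": 0.2, "B": 0.8}], self.groups(), 100.0, rng
        )
        differential_inclusion([ev], jc, self.groups(), "A", "B")
        assert ev.significant and ev.delta_psi > 0.5

    def test_undercovered_event_untestable(self):
        ev, jc = exact_psi_junctions({"A0": 0.5, "B0": 0.5, "B1": 0.5, "B2": 0.5, "B3": 0.5})
        differential_inclusion([ev], jc, self.groups(), "A", "B")
        assert not ev.testable and not ev.significant


class TestRepartition:
    def make_events(self, spec):
        out = []
        for i, (gene, ev_type, sig) in enumerate(spec):
            ev = SpliceEvent(f"e{i}", gene, ev_type, {}, [], [])
            ev.significant = sig
            out.append(ev)
        return out

    def test_single_ce_in_ten_gene_panel(self):
        events = self.make_events([("p1", "CE", True)])
        panel = {f"p{i}" for i in range(10)}
        table = event_repartition(events, panel, universe=panel | {"b1"})
        assert table.loc["CE", "panel_events"] == 1
        assert table.loc["CE", "panel_pct_genes"] == pytest.approx(10.0)

    def test_multi_event_gene_counts_once_in_percentage(self):
        events = self.make_events(
            [("p1", "CE", True), ("p1", "CE", True), ("p1", "CE", True)]
        )
        panel = {f"p{i}" for i in range(10)}
        table = event_repartition(events, panel, universe=panel)
        assert table.loc["CE", "panel_events"] == 3
        assert table.loc["CE", "panel_pct_genes"] == pytest.approx(10.0)

    def test_toy_counts_match_enumeration(self):
        spec = [
            ("p1", "CE", True),
            ("p2", "RI", True),
            ("p2", "CE", False),
            ("b1", "CE", True),
            ("b2", "MXE", True),
            ("b2", "MXE", True),
        ]
        events = self.make_events(spec)
        panel = {"p1", "p2", "p3", "p4"}
        universe = panel | {"b1", "b2", "b3", "b4", "b5"}
        table = event_repartition(events, panel, universe)
        assert table.loc["CE", "panel_events"] == 1
        assert table.loc["RI", "panel_pct_genes"] == pytest.approx(25.0)
        assert table.loc["MXE", "background_events"] == 2
        assert table.loc["MXE", "background_pct_genes"] == pytest.approx(20.0)
        assert table.loc["CE", "background_pct_genes"] == pytest.approx(20.0)

    def test_empty_panel_still_reports_background(self):
        events = self.make_events([("b1", "CE", True)])
        table = event_repartition(events, set(), universe={"b1", "b2"})
        assert np.isnan(table.loc["CE", "panel_pct_genes"])
        assert table.loc["CE", "background_pct_genes"] == pytest.approx(50.0)
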