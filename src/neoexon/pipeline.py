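"""End-to-end orchestration: simulate → DE → splicing → discovery → panel.

The pipeline mirrors a three-timepoint maturation design: the "early"
contrast compares the first two timepoints, the "late" contrast the last
two.  A :class:`RunReport` collects per-stage counts, including the
novel-exon candidate funnel, and is serialized as JSON next to the stage
outputs.  Identical configuration and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import GeneAnnotation, gene_characteristics
from .diffexpr import NegativeBinomialDE, stage_comparison
from .io import (
    write_bedgraph,
    write_counts,
    write_fasta,
    write_gtf,
    write_junctions,
)
from .novel_exon import (
    ThresholdConfig,
    filter_candidates,
    find_new_boundary_exons,
    funnel_counts,
    orf_consequence,
)
from .panel import compare_panel, intersect_de_as
from .simulate import SimulationConfig, default_config, simulate_all
from .splicing import (
    DifferentialInclusion,
    classify_annotation,
    event_repartition,
    events_frame,
)

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "de", "splice", "discover", "panel")


@dataclass
class PipelineConfig:
    out_dir: str = "neoexon_run"
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    simulation: SimulationConfig | None = None
    panel_genes: tuple[str, ...] = ()

    def resolved_simulation(self) -> SimulationConfig:
        if self.simulation is not None:
            return dataclasses.replace(self.simulation, seed=self.seed)
        return default_config(self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"]["canonical_pairs"] = sorted(
            list(p) for p in self.thresholds.canonical_pairs
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and d["thresholds"] is not None:
            t = dict(d["thresholds"])
            if "canonical_pairs" in t:
                t["canonical_pairs"] = frozenset(tuple(p) for p in t["canonical_pairs"])
            d["thresholds"] = ThresholdConfig(**t)
        if d.get("simulation") is not None:
            from .simulate import NovelExonSpec, PlantedDE, PlantedEvent

            s = dict(d["simulation"])
            s["planted_de"] = tuple(PlantedDE(**x) for x in s.get("planted_de", ()))
            s["planted_events"] = tuple(
                PlantedEvent(**x) for x in s.get("planted_events", ())
            )
            s["planted_novel_exons"] = tuple(
                NovelExonSpec(**x) for x in s.get("planted_novel_exons", ())
            )
            s["timepoints"] = tuple(s.get("timepoints", ("E18.5", "2w", "7w")))
            d["simulation"] = SimulationConfig(**s)
        d["stages"] = tuple(d.get("stages", ALL_STAGES))
        d["panel_genes"] = tuple(d.get("panel_genes", ()))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        # output location is provenance, not configuration: identical
        # analyses into different directories hash identically
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def validate_config(config: PipelineConfig) -> list[str]:
    """Problems preventing a run; empty list iff runnable."""
    problems: list[str] = []
    if not config.out_dir:
        problems.append("out_dir: output directory must be set")
    for s in config.stages:
        if s not in ALL_STAGES:
            problems.append(f"stages: unknown stage {s!r}; choose from {ALL_STAGES}")
    try:
        t = config.thresholds
        if t.min_mean_coverage <= 0 or t.min_background_ratio <= 0:
            problems.append("thresholds: filter thresholds must be positive")
    except ValueError as exc:
        problems.append(f"thresholds: {exc}")
    if "simulate" not in config.stages and any(
        s in config.stages for s in ("de", "splice", "discover", "panel")
    ):
        problems.append(
            "stages: downstream stages require the simulate stage in this "
            "configuration (file-based inputs go through the subcommand CLI)"
        )
    if not isinstance(config.seed, int) or config.seed < 0:
        problems.append("seed: must be a non-negative integer")
    return problems


@dataclass
class RunReport:
    version: str
    seed: int
    config_hash: str
    stages_run: list[str]
    de: dict = field(default_factory=dict)
    splicing: dict = field(default_factory=dict)
    funnel: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> RunReport:
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        stages_run=list(config.stages),
    )
    sim_config = config.resolved_simulation()

    sim = None
    try:
        if "simulate" in config.stages:
            sim = simulate_all(sim_config)
            _write_simulation(sim, out)
        timepoints = sim_config.timepoints
        contrasts = {
            "early": (timepoints[0], timepoints[1]),
            "late": (timepoints[1], timepoints[2]) if len(timepoints) > 2 else None,
        }
        de_results: dict[str, pd.DataFrame] = {}
        if "de" in config.stages and sim is not None:
            for stage, pair in contrasts.items():
                if pair is None:
                    continue
                res = NegativeBinomialDE(sim.counts, *pair).fit()
                de_results[stage] = res.frame
                res.frame.to_csv(out / f"de_{stage}.tsv", sep="\t", index_label="gene_id")
                report.de[stage] = {
                    "n_significant": int(res.frame["significant"].sum()),
                    "n_up": int(
                        (res.frame["significant"] & (res.frame["direction"] == "up")).sum()
                    ),
                    "n_down": int(
                        (res.frame["significant"] & (res.frame["direction"] == "down")).sum()
                    ),
                }
            if "early" in de_results and "late" in de_results:
                cmp = stage_comparison(de_results["early"], de_results["late"])
                report.de["stage_overlap"] = {
                    "n_overlap": len(cmp.overlap),
                    "consistent_fraction": cmp.consistent_fraction,
                }

        as_genes_by_stage: dict[str, set[str]] = {}
        if "splice" in config.stages and sim is not None:
            events = classify_annotation(sim.reference)
            for stage, pair in contrasts.items():
                if pair is None:
                    continue
                stage_events = classify_annotation(sim.reference)
                DifferentialInclusion(
                    stage_events, sim.junctions, sim.counts.groups, *pair
                ).fit()
                frame = events_frame(stage_events)
                frame.to_csv(out / f"events_{stage}.tsv", sep="\t", index=False)
                sig = frame[frame["significant"]]
                as_genes_by_stage[stage] = set(sig["gene_id"])
                report.splicing[stage] = {
                    "n_events": len(frame),
                    "n_significant": int(frame["significant"].sum()),
                    "by_type": sig.groupby("event_type").size().to_dict(),
                    "n_genes": int(sig["gene_id"].nunique()),
                }
                if config.panel_genes:
                    rep = event_repartition(
                        stage_events, set(config.panel_genes), set(sim.reference.genes)
                    )
                    rep.to_csv(out / f"repartition_{stage}.tsv", sep="\t")

        if "discover" in config.stages and sim is not None:
            candidates = find_new_boundary_exons(sim.assembled, sim.reference)
            genomes = {g.name: g for g in sim.genomes}
            filter_candidates(
                candidates,
                sim.pooled_coverage,
                genomes,
                sim.reference,
                config.thresholds,
                sim.assembled,
            )
            frame = _candidates_frame(candidates, sim, genomes)
            frame.to_csv(out / "candidates.tsv", sep="\t", index=False)
            with open(out / "novel_exons.bed", "w") as fh:
                for c in candidates:
                    if c.verdict:
                        fh.write(
                            f"{c.interval.seq_name}\t{c.interval.start}\t"
                            f"{c.interval.end}\t{c.host_gene}\t0\t{c.interval.strand}\n"
                        )
            report.funnel = funnel_counts(candidates)
            _assert_funnel_monotone(report.funnel)

        if "panel" in config.stages and sim is not None:
            chars = gene_characteristics(sim.reference)
            # expression: mean normalized count in the adult (last) group
            adult = sim.counts.samples_in_group(timepoints[-1])
            expr = sim.counts.counts[adult].mean(axis=1)
            chars["expression"] = expr.reindex(chars.index)
            panel = set(config.panel_genes) or {
                g for g in sim.reference.genes if g.startswith(("AS_", "NV"))
            }
            comparison = compare_panel(chars, panel)
            comparison.to_csv(out / "panel_comparison.tsv", sep="\t")
            report.panel["n_panel"] = len(panel)
            report.panel["characteristics"] = {
                ch: {"p": float(row["p"]), "direction": row["direction"]}
                for ch, row in comparison.iterrows()
            }
            if de_results and as_genes_by_stage:
                de_all = set().union(
                    *(set(f.index[f["significant"]]) for f in de_results.values())
                )
                as_all = set().union(*as_genes_by_stage.values())
                inter = intersect_de_as(de_all, as_all)
                report.panel["de_as_intersection"] = {
                    "n_both": len(inter.both),
                    "pct_of_de": inter.pct_of_de,
                    "pct_of_as": inter.pct_of_as,
                }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    (out / "report.json").write_text(report.to_json())
    return report


def _assert_funnel_monotone(funnel: dict[str, int]) -> None:
    order = ["new_boundary", "post_coverage", "post_background_ratio", "post_canonical_sites"]
    values = [funnel[k] for k in order if k in funnel]
    if any(b > a for a, b in zip(values, values[1:])):
        raise AssertionError(f"candidate funnel not monotone: {funnel}")


def _candidates_frame(candidates, sim, genomes) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "seq_name": c.interval.seq_name,
            "start": c.interval.start,
            "end": c.interval.end,
            "strand": c.interval.strand,
            "host_gene": c.host_gene,
            "transcript_id": c.transcript_id,
            "boundary_status": c.boundary_status,
            "fully_novel": c.fully_novel,
            "mean_coverage": c.mean_coverage,
            "background_coverage": c.background_coverage,
            "background_ratio": c.background_ratio,
            "donor": c.donor,
            "acceptor": c.acceptor,
            "canonical": c.canonical,
            "flanking_ratio": c.flanking_ratio,
            "verdict": c.verdict,
        }
        for name, ok in c.filter_trail:
            row[f"filter_{name}"] = ok
        host = sim.reference.genes.get(c.host_gene)
        coding = (
            next((t for t in host.transcripts.values() if t.cds), None) if host else None
        )
        if coding is not None and c.fully_novel:
            orf = orf_consequence(c, coding, genomes[c.interval.seq_name])
            row.update(
                {
                    "frame_preserving": orf.frame_preserving,
                    "premature_stop": orf.premature_stop,
                    "novel_aa_before_stop": orf.novel_aa_before_stop,
                }
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _write_simulation(sim, out: Path) -> None:
    data = out / "data"
    data.mkdir(exist_ok=True)
    write_fasta(sim.genomes, data / "genome.fa")
    write_gtf(sim.reference, data / "reference.gtf")
    write_gtf(sim.assembled, data / "assembled.gtf", source="assembly")
    for sample, track in sim.coverage.items():
        write_bedgraph(track, data / f"coverage_{sample}.bedgraph")
    write_bedgraph(sim.pooled_coverage, data / "coverage_pooled.bedgraph")
    write_junctions(sim.junctions, data / "junctions.tsv")
    write_counts(sim.counts, data / "counts.tsv", data / "groups.tsv")
    for name, table in sim.truth.items():
        table.to_csv(data / f"truth_{name}.tsv", sep="\t", index=False)
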