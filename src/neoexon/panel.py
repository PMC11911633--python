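"""Gene-panel characterization and gene-set summaries.

Compares structural/expression characteristics of a curated gene panel
(e.g. myopathy-associated genes) against the remaining protein-coding
background with a two-sided Mann–Whitney U test, partitions DE and AS gene
sets, and performs hypergeometric over-representation analysis on GMT gene
sets with Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


@dataclass
class CharacteristicComparison:
    characteristic: str
    panel_median: float
    background_median: float
    u_statistic: float
    p: float
    direction: str  # "higher" | "lower" | "equal" (panel vs background)


def compare_characteristic(
    panel_values, background_values, characteristic: str = ""
) -> CharacteristicComparison:
    """Two-sided Mann–Whitney U comparison of a per-gene characteristic.

    Uses the exact null when both samples have at most 12 values and no
    ties span the groups, the tie-corrected normal approximation otherwise.
    Missing values are dropped before testing.
    """
    a = np.asarray(panel_values, dtype=float)
    b = np.asarray(background_values, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both value lists must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        u = len(a) * len(b) / 2.0
        p = 1.0
    else:
        has_ties = len(np.unique(pooled)) < len(pooled)
        method = "exact" if (len(a) <= 12 and len(b) <= 12 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u, p = float(res.statistic), float(min(res.pvalue, 1.0))
    med_a, med_b = float(np.median(a)), float(np.median(b))
    direction = "higher" if med_a > med_b else ("lower" if med_a < med_b else "equal")
    return CharacteristicComparison(characteristic, med_a, med_b, u, p, direction)


def compare_panel(
    table: pd.DataFrame, panel: set[str], characteristics: list[str] | None = None
) -> pd.DataFrame:
    """Run :func:`compare_characteristic` for each column of a per-gene table."""
    characteristics = characteristics or list(table.columns)
    in_panel = table.index.isin(panel)
    rows = []
    for ch in characteristics:
        cmp = compare_characteristic(
            table.loc[in_panel, ch], table.loc[~in_panel, ch], ch
        )
        rows.append(vars(cmp))
    return pd.DataFrame(rows).set_index("characteristic")


@dataclass
class SetIntersection:
    de_only: set[str]
    as_only: set[str]
    both: set[str]
    pct_of_de: float  # integer-rounded percentage of DE genes also AS
    pct_of_as: float


def intersect_de_as(de_genes: set[str], as_genes: set[str]) -> SetIntersection:
    """Partition DE and AS gene sets and report both-set percentages."""
    both = de_genes & as_genes
    return SetIntersection(
        de_only=de_genes - as_genes,
        as_only=as_genes - de_genes,
        both=both,
        pct_of_de=round(100.0 * len(both) / len(de_genes)) if de_genes else float("nan"),
        pct_of_as=round(100.0 * len(both) / len(as_genes)) if as_genes else float("nan"),
    )


def ora_enrichment(
    study_set: set[str], universe: set[str], gene_sets: dict[str, set[str]]
) -> pd.DataFrame:
    """Hypergeometric over-representation of a study set in GMT gene sets.

    Each set is intersected with the universe; the upper-tail p-value is
    P(X >= overlap) for X ~ Hypergeom(|universe|, |set|, |study|).  Sets
    with zero overlap are still reported; BH adjustment spans all sets.
    """
    extra = study_set - universe
    if extra:
        raise ValueError(f"study genes outside universe: {sorted(extra)[:5]}")
    rows = []
    m = len(universe)
    n_study = len(study_set)
    for name, members in gene_sets.items():
        in_universe = members & universe
        overlap = len(in_universe & study_set)
        k = len(in_universe)
        expected = k * n_study / m if m else float("nan")
        p = float(stats.hypergeom.sf(overlap - 1, m, k, n_study)) if m else 1.0
        rows.append(
            {
                "gene_set": name,
                "set_size": k,
                "overlap": overlap,
                "expected": expected,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["padj"] = bh_adjust(df["p"].to_numpy())
        df = df.set_index("gene_set")
    return df


def splicing_gene_audit(
    rna_splicing_set: set[str],
    de_genes_by_stage: dict[str, set[str]],
    as_genes_by_stage: dict[str, set[str]],
) -> pd.DataFrame:
    """Tally how many genes of a functional set show DE and AS per stage."""
    stages = sorted(set(de_genes_by_stage) | set(as_genes_by_stage))
    rows = []
    for stage in stages:
        rows.append(
            {
                "stage": stage,
                "n_de": len(rna_splicing_set & de_genes_by_stage.get(stage, set())),
                "n_as": len(rna_splicing_set & as_genes_by_stage.get(stage, set())),
            }
        )
    return pd.DataFrame(rows).set_index("stage")
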