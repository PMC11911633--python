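"""Negative-binomial differential expression between two sample groups.

This is a deliberately plain NB Wald test — median-of-ratios normalization,
gene-wise method-of-moments dispersion, a Wald statistic on the log2 fold
change referred to a t distribution — without dispersion shrinkage, trend
fitting, Cook's filtering or independent filtering.  Significance uses the
strict thresholds adjusted p < 0.05 and |log2FC| > 1.

The model surface follows the statsmodels idiom::

    res = NegativeBinomialDE(counts, "E18.5", "2w").fit()
    res.frame            # per-gene estimates
    res.significant_genes
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CountMatrix

log = logging.getLogger(__name__)

PADJ_THRESHOLD = 0.05
LFC_THRESHOLD = 1.0
PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8

DE_COLUMNS = ["base_mean", "log2fc", "p", "padj", "significant", "direction"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    Genes with any zero count are excluded from the reference; if no gene is
    zero-free, the reference falls back to genes with at most 50% zeros,
    with the geometric mean taken over their positive counts.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    mat = df.to_numpy(dtype=float)
    if mat.shape[0] == 0:
        raise ValueError("empty count matrix")
    zero_free = (mat > 0).all(axis=1)
    if zero_free.any():
        sub = mat[zero_free]
        ref = np.exp(np.log(sub).mean(axis=1))
        ratios = sub / ref[:, None]
        factors = np.median(ratios, axis=0)
    else:
        frac_zero = (mat == 0).mean(axis=1)
        usable = frac_zero <= 0.5
        if not usable.any():
            raise ValueError("no gene with at most 50% zero counts; cannot normalize")
        log.warning(
            "no zero-free gene; falling back to %d genes with <=50%% zeros",
            int(usable.sum()),
        )
        sub = mat[usable]
        logs = np.full(sub.shape, np.nan)
        np.log(sub, out=logs, where=sub > 0)
        ref = np.exp(np.nanmean(logs, axis=1))
        ratios = np.where(sub > 0, sub / ref[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("non-positive size factor estimated")
    return pd.Series(factors, index=df.columns, name="size_factor")


def _moment_dispersion(y: np.ndarray, group_cols: list[np.ndarray]) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per gene."""
    num = np.zeros(y.shape[0])
    den = np.zeros(y.shape[0])
    for cols in group_cols:
        sub = y[:, cols]
        n = sub.shape[1]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        a = np.zeros_like(m)
        a[ok] = (v[ok] - m[ok]) / m[ok] ** 2
        num += np.where(ok, a * (n - 1), 0.0)
        den += np.where(ok, float(n - 1), 0.0)
    disp = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return np.maximum(disp, DISPERSION_FLOOR)


class NegativeBinomialDE:
    """Two-group NB Wald differential-expression model.

    Parameters
    ----------
    counts : CountMatrix
        Integer counts with group labels; both requested groups need at
        least two replicates.
    group_a, group_b : str
        Reference and comparison group; log2FC is B over A.
    """

    def __init__(self, counts: CountMatrix, group_a: str, group_b: str) -> None:
        self.counts = counts.subset_groups(group_a, group_b)
        self.group_a = group_a
        self.group_b = group_b
        for g in (group_a, group_b):
            if len(self.counts.samples_in_group(g)) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 replicates")

    def fit(self) -> "DEResults":
        df = self.counts.counts
        sf = size_factors(df)
        # anchor units to the first sample so normalization absorbs a
        # rescaling of any other sample exactly
        sf = sf / sf.iloc[0]
        y = df.to_numpy(dtype=float) / sf.to_numpy()[None, :]

        cols_a = np.array(
            [df.columns.get_loc(s) for s in self.counts.samples_in_group(self.group_a)]
        )
        cols_b = np.array(
            [df.columns.get_loc(s) for s in self.counts.samples_in_group(self.group_b)]
        )
        n_a, n_b = len(cols_a), len(cols_b)

        tested = df.to_numpy().sum(axis=1) > 0  # all-zero genes excluded
        m_a = y[:, cols_a].mean(axis=1)
        m_b = y[:, cols_b].mean(axis=1)
        disp = _moment_dispersion(y, [cols_a, cols_b])

        log2fc = np.log2((m_b + PSEUDOCOUNT) / (m_a + PSEUDOCOUNT))
        ln2sq = np.log(2.0) ** 2
        var_a = (m_a + disp * m_a**2) / n_a / ((m_a + PSEUDOCOUNT) ** 2 * ln2sq)
        var_b = (m_b + disp * m_b**2) / n_b / ((m_b + PSEUDOCOUNT) ** 2 * ln2sq)
        se = np.sqrt(var_a + var_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            wald = np.where(se > 0, log2fc / se, 0.0)
        p = 2.0 * stats.t.sf(np.abs(wald), df=n_a + n_b - 2)

        frame = pd.DataFrame(
            {
                "base_mean": y.mean(axis=1),
                "log2fc": log2fc,
                "p": np.where(tested, p, np.nan),
                "padj": np.nan,
                "significant": False,
                "direction": np.where(log2fc > 0, "up", "down"),
            },
            index=df.index,
        )
        if tested.any():
            frame.loc[tested, "padj"] = bh_adjust(p[tested])
        sig = (frame["padj"] < PADJ_THRESHOLD) & (
            frame["log2fc"].abs() > LFC_THRESHOLD
        )
        frame["significant"] = sig.fillna(False)
        return DEResults(frame, self.group_a, self.group_b, sf)


@dataclass
class DEResults:
    """Per-gene DE estimates from :class:`NegativeBinomialDE.fit`."""

    frame: pd.DataFrame
    group_a: str
    group_b: str
    size_factors: pd.Series

    @property
    def significant_genes(self) -> set[str]:
        return set(self.frame.index[self.frame["significant"]])

    def directions(self) -> pd.Series:
        return self.frame.loc[self.frame["significant"], "direction"]

    def summary(self) -> str:
        f = self.frame
        n_tested = int(f["p"].notna().sum())
        n_sig = int(f["significant"].sum())
        n_up = int((f["significant"] & (f["direction"] == "up")).sum())
        lines = [
            f"NB Wald differential expression: {self.group_b} vs {self.group_a}",
            f"  genes tested:      {n_tested} (of {len(f)})",
            f"  significant:       {n_sig}  (padj<{PADJ_THRESHOLD}, |log2FC|>{LFC_THRESHOLD})",
            f"  up / down:         {n_up} / {n_sig - n_up}",
        ]
        return "\n".join(lines)


def nb_wald_test(counts: CountMatrix, group_a: str, group_b: str) -> pd.DataFrame:
    """Functional wrapper: fit the two-group NB Wald model, return the frame."""
    return NegativeBinomialDE(counts, group_a, group_b).fit().frame


@dataclass
class StageComparison:
    """Overlap between two stages' significant DE gene sets."""

    early_set: set[str]
    late_set: set[str]
    overlap: set[str] = field(init=False)
    consistent_fraction: float = field(init=False)

    def __post_init__(self) -> None:
        self.overlap = self.early_set & self.late_set
        self.consistent_fraction = float("nan")


def stage_comparison(early: pd.DataFrame, late: pd.DataFrame) -> StageComparison:
    """Compare early- and late-stage DE calls.

    ``consistent_fraction`` is the share of genes significant at both stages
    whose fold-change direction agrees; NaN when the overlap is empty.
    """
    early_sig = set(early.index[early["significant"]])
    late_sig = set(late.index[late["significant"]])
    cmp = StageComparison(early_sig, late_sig)
    if cmp.overlap:
        same = sum(
            1
            for g in cmp.overlap
            if early.loc[g, "direction"] == late.loc[g, "direction"]
        )
        cmp.consistent_fraction = same / len(cmp.overlap)
    return cmp
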