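"""Expression-side statistics: CPM, a simplified DE test, BH FDR,
correlations, and between-group expression-shift tests.

The differential-expression routine is a deliberately simple stand-in for a
negative-binomial count model: it tests log2(CPM + pseudocount) between
conditions with Welch's t and adjusts with Benjamini-Hochberg.  With few
replicates it is conservative, so the pipeline also accepts a precomputed
external DE table (gene, log2fc, fdr) produced by a dedicated count-model
tool.  Thresholding (default FDR 0.05 and |log2FC| > 0.5), grouping and the
shift tests are independent of which DE route supplied the table.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preference import PreferenceRecord


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million per sample (column)."""
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"zero library size for sample(s) {bad}")
    return counts * 1e6 / libs


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class GroupShiftResult:
    """Welch's t comparison of two value vectors (e.g. per-gene log2 FCs)."""

    t: float
    df: float
    p: float
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    group_x: int | None = None
    group_y: int | None = None

    def summary(self) -> dict:
        return {
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "n_x": self.n_x,
            "n_y": self.n_y,
            "mean_x": self.mean_x,
            "mean_y": self.mean_y,
            "group_x": self.group_x,
            "group_y": self.group_y,
        }


def welch_t(x: Sequence[float], y: Sequence[float]) -> GroupShiftResult:
    """Welch's unequal-variance t-test, two-sided, Welch-Satterthwaite df."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 2 or ya.size < 2:
        raise ValueError("welch_t needs at least 2 values per sample")
    if not (np.isfinite(xa).all() and np.isfinite(ya).all()):
        raise ValueError("welch_t requires finite values")
    vx, vy = xa.var(ddof=1), ya.var(ddof=1)
    nx, ny = xa.size, ya.size
    se2 = vx / nx + vy / ny
    if se2 == 0:
        # both samples constant
        t = 0.0 if xa.mean() == ya.mean() else math.copysign(math.inf, xa.mean() - ya.mean())
        df = float(nx + ny - 2)
        p = 1.0 if t == 0.0 else 0.0
    else:
        t = float((xa.mean() - ya.mean()) / math.sqrt(se2))
        df = float(
            se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        )
        p = float(2 * stats.t.sf(abs(t), df))
    return GroupShiftResult(t, df, p, nx, ny, float(xa.mean()), float(ya.mean()))


def rank_correlation(
    a: Sequence[float], b: Sequence[float], method: str = "spearman"
) -> float:
    """Spearman rho (average-rank ties) or Pearson r.

    Constant input yields NaN with a warning rather than an error.
    """
    aa = np.asarray(a, dtype=float)
    ba = np.asarray(b, dtype=float)
    if aa.size != ba.size or aa.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(aa == aa[0]) or np.all(ba == ba[0]):
        warnings.warn("correlation undefined for a constant vector; returning NaN")
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "spearman":
            rho = stats.spearmanr(aa, ba).statistic
        elif method == "pearson":
            rho = stats.pearsonr(aa, ba).statistic
        else:
            raise ValueError(f"unknown method {method!r}")
    return float(rho)


def classify_de(
    log2fc: float, fdr: float, fdr_thresh: float = 0.05, lfc_thresh: float = 0.5
) -> str:
    """'up' / 'down' / 'ns' at the given FDR and log2FC thresholds."""
    if not math.isnan(fdr) and fdr < fdr_thresh:
        if log2fc > lfc_thresh:
            return "up"
        if log2fc < -lfc_thresh:
            return "down"
    return "ns"


def de_table(
    counts: pd.DataFrame,
    control_samples: Sequence[str],
    treated_samples: Sequence[str],
    pseudocount: float = 0.5,
    fdr_thresh: float = 0.05,
    lfc_thresh: float = 0.5,
) -> pd.DataFrame:
    """Per-gene log2FC (treated vs control), Welch p on log2(CPM + pc),
    BH FDR and DE class.

    With fewer than 2 replicates on either side, p and fdr are NaN and only
    the fold change is reported (de_class 'ns').
    """
    control_samples = list(control_samples)
    treated_samples = list(treated_samples)
    if set(control_samples) & set(treated_samples):
        raise ValueError("control and treated sample sets overlap")
    missing = (set(control_samples) | set(treated_samples)) - set(counts.columns)
    if missing:
        raise ValueError(f"samples not in count matrix: {sorted(missing)}")
    logcpm = np.log2(cpm(counts) + pseudocount)
    lc = logcpm[control_samples].to_numpy()
    lt = logcpm[treated_samples].to_numpy()
    log2fc = lt.mean(axis=1) - lc.mean(axis=1)
    if len(control_samples) >= 2 and len(treated_samples) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ttest_ind(lt, lc, axis=1, equal_var=False)
        p = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
        fdr = bh_fdr(p)
    else:
        p = np.full(len(log2fc), np.nan)
        fdr = np.full(len(log2fc), np.nan)
    de_class = [
        classify_de(l, q, fdr_thresh, lfc_thresh) for l, q in zip(log2fc, fdr)
    ]
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "de_class": de_class},
        index=counts.index.rename("gene_id"),
    )


def group_expression_shift(
    records: Sequence[PreferenceRecord],
    de: pd.DataFrame,
    group_x: int,
    group_y: int,
) -> GroupShiftResult:
    """Welch's t between the per-gene log2 FCs of two preference groups.

    Records must carry associated gene ids; each gene contributes once per
    group.  A negative t means group_x is the more downregulated one.
    """
    def genes_of(group: int) -> list[str]:
        seen: dict[str, None] = {}
        for r in records:
            if r.group == group:
                for g in r.genes:
                    seen.setdefault(g, None)
        return [g for g in seen if g in de.index]

    gx = genes_of(group_x)
    gy = genes_of(group_y)
    if not gx or not gy:
        raise ValueError(
            f"empty group after gene join (group {group_x}: {len(gx)}, "
            f"group {group_y}: {len(gy)})"
        )
    res = welch_t(de.loc[gx, "log2fc"].to_numpy(), de.loc[gy, "log2fc"].to_numpy())
    return GroupShiftResult(
        res.t, res.df, res.p, res.n_x, res.n_y, res.mean_x, res.mean_y,
        group_x=group_x, group_y=group_y,
    )


def mean_replicate_fc(fc_tables: Sequence[Mapping[str, float]]) -> dict[str, float]:
    """Average per-gene fold changes over biological replicates.

    Genes present in only some replicates are averaged over those present.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for table in fc_tables:
        for gene, fc in table.items():
            sums[gene] = sums.get(gene, 0.0) + fc
            counts[gene] = counts.get(gene, 0) + 1
    return {g: sums[g] / counts[g] for g in sums}
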