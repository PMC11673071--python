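"""Wilcoxon rank-sum differential expression and NP-count regression.

DGE between co-expression strata follows the widely used single-cell
defaults: genes must be detected in at least ``min_pct`` of one group
and show |ln fold change| >= ``min_abs_logfc`` before testing; a
two-sided rank-sum p-value is computed per surviving gene and
Benjamini-Hochberg FDR is applied over the surviving genes of the
contrast.  Pseudo-bulk aggregation is deliberately not offered.

The regression path fits, per gene, an ordinary least squares line of
expression on the per-cell NP co-expression count and ranks genes by
slope and by R^2 to surface the programs that scale with NP load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DGEFilter:
    min_pct: float = 0.1
    min_abs_logfc: float = 0.25

    def __post_init__(self) -> None:
        if not (0 <= self.min_pct < 1):
            raise ValidationError("min_pct must lie in [0, 1)")
        if self.min_abs_logfc < 0:
            raise ValidationError("min_abs_logfc must be non-negative")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _delog(values: np.ndarray, layer: str) -> np.ndarray:
    # log layers in this package are log2(x + 1)
    return np.exp2(values) - 1.0 if layer.startswith("log") else values


def wilcoxon_dge(
    matrix: GeneExpressionMatrix,
    group_a_ids,
    group_b_ids,
    dge_filter: DGEFilter | None = None,
    exact_max_n: int = 50,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DGE of group A over group B on a log layer.

    Fold change is the natural log of the ratio of (mean de-logged
    expression + 1) between the groups.  The exact rank-sum
    distribution is used when both groups have <= ``exact_max_n`` cells
    and the pooled values are tie-free; otherwise the normal
    approximation with tie and continuity corrections.
    """
    dge_filter = dge_filter or DGEFilter()
    if not matrix.layer.startswith("log"):
        raise ValidationError("wilcoxon_dge expects a log-normalized layer")
    group_a_ids, group_b_ids = list(group_a_ids), list(group_b_ids)
    overlap = set(group_a_ids) & set(group_b_ids)
    if overlap:
        raise ValidationError(f"groups overlap: {sorted(overlap)[:5]}")
    if not group_a_ids or not group_b_ids:
        raise ValidationError("both groups must be non-empty")

    a = matrix.data.loc[:, group_a_ids].to_numpy(dtype=float)
    b = matrix.data.loc[:, group_b_ids].to_numpy(dtype=float)
    pct_a = (a > 0).mean(axis=1)
    pct_b = (b > 0).mean(axis=1)
    mean_a = _delog(a, matrix.layer).mean(axis=1)
    mean_b = _delog(b, matrix.layer).mean(axis=1)
    log_fc = np.log((mean_a + 1.0) / (mean_b + 1.0))

    survives = (np.maximum(pct_a, pct_b) >= dge_filter.min_pct) & (np.abs(log_fc) >= dge_filter.min_abs_logfc)
    if not survives.any():
        logger.warning("wilcoxon_dge: no genes survive filters")
        return pd.DataFrame(columns=["gene", "log_fc", "p_value", "fdr", "pct_a", "pct_b"])

    genes = np.array(matrix.gene_ids)[survives]
    p_values = np.empty(len(genes))
    small = len(group_a_ids) <= exact_max_n and len(group_b_ids) <= exact_max_n
    for i, row in enumerate(np.nonzero(survives)[0]):
        av, bv = a[row], b[row]
        pooled = np.concatenate([av, bv])
        if np.ptp(pooled) == 0:
            p_values[i] = 1.0
            continue
        tie_free = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (small and tie_free) else "asymptotic"
        p_values[i] = stats.mannwhitneyu(av, bv, alternative="two-sided", method=method,
                                         use_continuity=True).pvalue
    out = pd.DataFrame({
        "gene": genes,
        "log_fc": log_fc[survives],
        "p_value": p_values,
        "fdr": bh_adjust(p_values),
        "pct_a": pct_a[survives],
        "pct_b": pct_b[survives],
    })
    return out.sort_values(["fdr", "p_value", "gene"], kind="mergesort").reset_index(drop=True)


def np_count_regression(
    matrix: GeneExpressionMatrix,
    profiles: pd.DataFrame,
    gene_subset=None,
) -> pd.DataFrame:
    """Per-gene OLS of log expression on NP co-expression count.

    Returns slope, R^2, two-sided slope p-value and BH FDR across the
    tested gene subset.
    """
    if "np_count" not in profiles.columns:
        raise ValidationError("profiles must carry np_count")
    obs = [o for o in matrix.obs_ids if o in profiles.index]
    if len(obs) < 3:
        raise ValidationError("need at least 3 cells")
    x = profiles.loc[obs, "np_count"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValidationError("np_count has zero variance")
    genes = list(gene_subset) if gene_subset is not None else matrix.gene_ids
    missing = [g for g in genes if g not in matrix.data.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing[:5]}")
    y = matrix.data.loc[genes, obs].to_numpy(dtype=float)

    n = len(obs)
    xc = x - x.mean()
    ssx = (xc ** 2).sum()
    yc = y - y.mean(axis=1, keepdims=True)
    slope = (yc @ xc) / ssx
    ssy = (yc ** 2).sum(axis=1)
    ss_reg = slope ** 2 * ssx
    with np.errstate(invalid="ignore", divide="ignore"):
        r_squared = np.where(ssy > 0, ss_reg / ssy, 0.0)
        resid_var = (ssy - ss_reg) / (n - 2)
        se = np.sqrt(resid_var / ssx)
        t = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    p = np.where(np.isfinite(t), 2 * stats.t.sf(np.abs(t), n - 2), 0.0)
    p = np.where(slope == 0, 1.0, p)
    out = pd.DataFrame({
        "gene": genes,
        "coefficient": slope,
        "r_squared": np.clip(r_squared, 0.0, 1.0),
        "p_value": p,
        "fdr": bh_adjust(p),
    })
    return out.reset_index(drop=True)


def rank_regression_hits(records: pd.DataFrame, top_n: int = 10) -> tuple[list[str], list[str]]:
    """Top genes by descending slope and by descending R^2; ties broken alphabetically."""
    if records.empty:
        raise ValidationError("no regression records to rank")
    by_coef = records.sort_values(["coefficient", "gene"], ascending=[False, True], kind="mergesort")
    by_r2 = records.sort_values(["r_squared", "gene"], ascending=[False, True], kind="mergesort")
    return list(by_coef["gene"].head(top_n)), list(by_r2["gene"].head(top_n))
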