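"""Per-cell neuropeptide co-expression scoring and stratification.

The central quantity is the per-cell NP co-expression count: the
number of distinct neuropeptide genes with nonzero expression in a
cell.  Because gene presence/absence is more conserved across studies
than exact transcript counts, this count serves as a proxy for a
cell's neuropeptide transcript load.  Cells are stratified into
low (0-1), mid (2-5) and high (6+) NP-producing groups, and donor-level
stratum proportions are compared across disease conditions with a
rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import AssociationResult, rank_sum_test, spearman
from .io import GeneExpressionMatrix, GeneList, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

STRATA = ("low", "mid", "high")


@dataclass
class QCThresholds:
    """Cell quality bounds: 200-2500 expressed genes, < 5% mitochondrial reads."""

    min_genes: int = 200
    max_genes: int = 2500
    max_mito_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.min_genes <= self.max_genes):
            raise ValidationError("require 0 < min_genes <= max_genes")
        if not (0 <= self.max_mito_fraction <= 1):
            raise ValidationError("max_mito_fraction must be a fraction in [0, 1]")


@dataclass
class StratumScheme:
    """Co-expression count cut points: low [0, low_max], mid (low_max, mid_max], high (mid_max, inf)."""

    low_max: int = 1
    mid_max: int = 5

    def __post_init__(self) -> None:
        if not (0 <= self.low_max < self.mid_max):
            raise ValidationError("require 0 <= low_max < mid_max")

    def assign(self, np_count) -> np.ndarray:
        counts = np.asarray(np_count)
        out = np.where(counts <= self.low_max, "low", np.where(counts <= self.mid_max, "mid", "high"))
        return out.astype(object)


def qc_filter(
    matrix: GeneExpressionMatrix,
    meta: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = "MT-",
) -> tuple[GeneExpressionMatrix, dict[str, int]]:
    """Drop cells outside the expressed-gene and mitochondrial-fraction bounds.

    Mitochondrial fraction comes from ``meta['pct_mito']`` when
    available, otherwise from genes whose symbol starts with
    ``mito_prefix``.  Returns the filtered matrix and a per-criterion
    removal tally (a cell can fail several criteria).
    """
    thresholds = thresholds or QCThresholds()
    if matrix.layer != "raw_counts":
        raise ValidationError("qc_filter expects the raw_counts layer")
    values = matrix.data.to_numpy()
    genes_expressed = (values > 0).sum(axis=0)

    if meta is not None and "pct_mito" in meta.columns:
        pct = meta["pct_mito"].reindex(matrix.obs_ids)
        mito_fraction = pd.to_numeric(pct, errors="coerce").to_numpy(dtype=float)
    else:
        mito_mask = np.array([g.startswith(mito_prefix.upper()) for g in matrix.gene_ids])
        totals = values.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mito_fraction = np.where(totals > 0, values[mito_mask].sum(axis=0) / totals, 0.0)
    mito_fraction = np.nan_to_num(mito_fraction, nan=0.0)

    too_few = genes_expressed < thresholds.min_genes
    too_many = genes_expressed > thresholds.max_genes
    too_mito = mito_fraction >= thresholds.max_mito_fraction
    keep = ~(too_few | too_many | too_mito)
    tally = {
        "input_cells": matrix.n_obs,
        "removed_min_genes": int(too_few.sum()),
        "removed_max_genes": int(too_many.sum()),
        "removed_mito": int(too_mito.sum()),
        "retained": int(keep.sum()),
    }
    logger.info("qc_filter: %s", tally)
    kept_ids = [o for o, k in zip(matrix.obs_ids, keep) if k]
    return matrix.subset_obs(kept_ids), tally


def cpm_normalize(matrix: GeneExpressionMatrix) -> GeneExpressionMatrix:
    """Scale each cell to one million total counts; all-zero cells stay zero and are flagged."""
    if matrix.layer != "raw_counts":
        raise ValidationError("cpm_normalize expects the raw_counts layer")
    values = matrix.data.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    zero = totals == 0
    scale = np.where(zero, 1.0, totals)
    cpm = values / scale * 1e6
    zero_obs = tuple(o for o, z in zip(matrix.obs_ids, zero) if z)
    if zero_obs:
        logger.warning("cpm_normalize: %d all-zero cells left unscaled", len(zero_obs))
    return GeneExpressionMatrix(
        pd.DataFrame(cpm, index=matrix.data.index, columns=matrix.data.columns), "cpm", zero_obs
    )


_LOG_LAYER = {"raw_counts": "log_raw", "cpm": "log_cpm", "tpm": "log_tpm"}


def log_transform(matrix: GeneExpressionMatrix, pseudocount: float = 1.0) -> GeneExpressionMatrix:
    """Element-wise log2(value + pseudocount)."""
    if matrix.layer not in _LOG_LAYER:
        raise ValidationError(f"layer {matrix.layer!r} is already log scale")
    values = matrix.data.to_numpy(dtype=float)
    if pseudocount <= 0 and (values == 0).any():
        raise ValidationError("pseudocount must be positive when zeros are present")
    logged = np.log2(values + pseudocount)
    return GeneExpressionMatrix(
        pd.DataFrame(logged, index=matrix.data.index, columns=matrix.data.columns),
        _LOG_LAYER[matrix.layer],
        matrix.zero_obs,
    )


def count_np_coexpression(
    matrix: GeneExpressionMatrix,
    np_list: GeneList,
    presence_matrix: GeneExpressionMatrix | None = None,
) -> pd.DataFrame:
    """Per-cell NP co-expression count and NP transcript sum.

    ``np_count`` is the number of NP genes with value > 0 (presence is
    judged on ``presence_matrix`` when given, e.g. raw counts while
    summing CPM); ``np_transcript_sum`` sums NP-gene values in
    ``matrix``'s declared layer.  Returns a DataFrame indexed by obs id
    with columns np_count, np_transcript_sum.
    """
    gene_set = {normalize_symbol(g) for g in matrix.gene_ids}
    present = [s for s in np_list.symbols if s in gene_set]
    absent = [s for s in np_list.symbols if s not in gene_set]
    if absent:
        logger.warning("count_np_coexpression: %d NP symbols absent from matrix: %s",
                       len(absent), absent[:10])
    if not present:
        raise ValidationError("no NP list symbols found in the matrix gene ids")
    sums = matrix.data.loc[present].to_numpy(dtype=float).sum(axis=0)
    source = presence_matrix if presence_matrix is not None else matrix
    counts = (source.data.loc[present].to_numpy() > 0).sum(axis=0)
    return pd.DataFrame(
        {"np_count": counts.astype(int), "np_transcript_sum": sums},
        index=pd.Index(matrix.obs_ids, name="obs_id"),
    )


def stratify(profiles: pd.DataFrame, scheme: StratumScheme | None = None) -> pd.DataFrame:
    """Assign each cell its stratum label; exhaustive and mutually exclusive."""
    scheme = scheme or StratumScheme()
    out = profiles.copy()
    out["stratum"] = scheme.assign(out["np_count"].to_numpy())
    return out


def np_count_abundance_correlation(profiles: pd.DataFrame) -> AssociationResult:
    """Spearman correlation between NP co-expression count and NP transcript sum."""
    return spearman(profiles["np_count"].to_numpy(), profiles["np_transcript_sum"].to_numpy())


def stratum_proportions(profiles: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Donor-level stratum proportions: cells in stratum / donor's total retained cells.

    Zero-cell strata are reported with proportion 0; donors with no
    retained cells are excluded with a warning.
    """
    if "stratum" not in profiles.columns:
        raise ValidationError("profiles must be stratified first")
    missing = [o for o in profiles.index if o not in meta.index]
    if missing:
        raise ValidationError(f"metadata missing for obs ids: {missing[:5]}")
    joined = profiles.join(meta[["donor_id", "condition"]])
    records = []
    for (donor, condition), group in joined.groupby(["donor_id", "condition"], sort=True):
        total = len(group)
        if total == 0:  # pragma: no cover - groupby never yields empty groups
            continue
        counts = group["stratum"].value_counts()
        for stratum in STRATA:
            n = int(counts.get(stratum, 0))
            records.append({
                "donor_id": donor, "condition": condition, "stratum": stratum,
                "n_cells": n, "proportion": n / total,
            })
    absent_donors = set(meta["donor_id"]) - set(joined["donor_id"])
    if absent_donors:
        logger.warning("stratum_proportions: donors with zero retained cells excluded: %s",
                       sorted(absent_donors))
    return pd.DataFrame(records)


def compare_stratum_proportions(
    records: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    stratum: str,
    alternative: str = "greater",
) -> AssociationResult:
    """Rank-sum test of donor-level stratum proportions between two conditions.

    Exact enumeration when both conditions have <= 10 donors, otherwise
    the normal approximation with tie and continuity corrections.
    """
    for condition in (condition_a, condition_b):
        if condition not in set(records["condition"]):
            raise ValidationError(f"condition {condition!r} absent from records")
    sub = records[records["stratum"] == stratum]
    a = sub.loc[sub["condition"] == condition_a].sort_values("donor_id")["proportion"].to_numpy()
    b = sub.loc[sub["condition"] == condition_b].sort_values("donor_id")["proportion"].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need at least 2 donors per condition")
    return rank_sum_test(a, b, alternative=alternative, exact_max_n=10)


def subsample_donors(
    meta: pd.DataFrame,
    per_condition_n: int,
    seed: int,
    conditions: list[str] | None = None,
) -> list[str]:
    """Seeded donor subsample giving each condition equal representation.

    Donors are taken in first-appearance order within each condition;
    when exactly ``per_condition_n`` are available they are all kept in
    input order, otherwise a seeded choice without replacement is made.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    conditions = conditions or list(dict.fromkeys(meta["condition"].dropna()))
    for condition in conditions:
        donors = list(dict.fromkeys(meta.loc[meta["condition"] == condition, "donor_id"]))
        if len(donors) < per_condition_n:
            raise ValidationError(
                f"condition {condition!r} has {len(donors)} donors, fewer than {per_condition_n}"
            )
        if len(donors) == per_condition_n:
            picked = donors
        else:
            picked = [donors[i] for i in sorted(rng.choice(len(donors), per_condition_n, replace=False))]
        logger.info("subsample_donors: %s -> %s", condition, picked)
        chosen.extend(picked)
    return chosen
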