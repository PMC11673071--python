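"""Age association of cumulative AD-neuropeptide expression in bulk brain RNA-seq.

Aging is proxied cross-sectionally ("pseudo-aging"): donors of
different ages at death stand in for a longitudinal series.  Per brain
region, the cumulative expression of the AD-associated neuropeptides
(sum over genes of log2(TPM + 1)) is correlated with donor age by a
partial Spearman correlation adjusting for RNA integrity (RIN) and the
Hardy death-circumstance score, after conservative sample exclusions:
complete age/sex/death metadata required, Hardy 3-4 (intermediate/slow
death) excluded, RIN must exceed 6, and donors aged 20-29 are dropped
because brain development continues into the third decade.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import AssociationResult, partial_spearman
from .io import GeneExpressionMatrix, GeneList, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

AGE_BRACKET_MIDPOINTS = {
    "20-29": 24.5, "30-39": 34.5, "40-49": 44.5, "50-59": 54.5,
    "60-69": 64.5, "70-79": 74.5, "80-89": 84.5,
}

REQUIRED_META = ("age", "sex", "hardy", "rin", "region")


def age_to_numeric(age) -> float:
    """Decade brackets (as large bulk consortia publish ages) map to midpoints; numbers pass through."""
    if isinstance(age, str) and age.strip() in AGE_BRACKET_MIDPOINTS:
        return AGE_BRACKET_MIDPOINTS[age.strip()]
    return float(age)


def filter_aging_samples(meta: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the bulk-sample exclusion gates; returns retained metadata and a tally.

    Gates (conjunctive, order-independent): complete age/sex/hardy
    metadata; Hardy not in {3, 4}; RIN strictly greater than 6; age not
    in the 20-29 bracket.
    """
    for col in REQUIRED_META:
        if col not in meta.columns:
            raise ValidationError(f"metadata missing required column {col!r}")
    age = meta["age"].map(lambda a: np.nan if pd.isna(a) else age_to_numeric(a))
    hardy = pd.to_numeric(meta["hardy"], errors="coerce")
    rin = pd.to_numeric(meta["rin"], errors="coerce")

    incomplete = age.isna() | meta["sex"].isna() | hardy.isna()
    bad_hardy = hardy.isin([3, 4]).fillna(False)
    bad_rin = ~(rin > 6)  # missing RIN fails the gate too
    bad_age = (age >= 20) & (age <= 29)
    keep = ~(incomplete | bad_hardy | bad_rin | bad_age.fillna(False))

    tally = {
        "input_samples": len(meta),
        "removed_incomplete_metadata": int(incomplete.sum()),
        "removed_hardy_3_4": int(bad_hardy.sum()),
        "removed_rin_le_6": int(bad_rin.sum()),
        "removed_age_20_29": int(bad_age.fillna(False).sum()),
        "retained": int(keep.sum()),
    }
    logger.info("filter_aging_samples: %s", tally)
    if tally["retained"] == 0:
        logger.warning("filter_aging_samples: no samples survive the exclusion gates")
    return meta.loc[keep], tally


def cumulative_adnp_expression(
    tpm: GeneExpressionMatrix,
    adnp_list: GeneList,
    mode: str = "sum_of_logs",
) -> pd.Series:
    """Cumulative ADNP expression per sample.

    Default is the sum over ADNP genes of log2(TPM + 1); ``mode=
    'log_of_sum'`` instead logs the summed TPM.  ADNP genes absent from
    the matrix contribute 0 and are warned about once.
    """
    gene_set = {normalize_symbol(g) for g in tpm.gene_ids}
    present = [s for s in adnp_list.symbols if s in gene_set]
    missing = [s for s in adnp_list.symbols if s not in gene_set]
    if missing:
        logger.warning("cumulative_adnp_expression: ADNP genes absent from matrix: %s", missing)
    if not present:
        raise ValidationError("no ADNP list genes found in the expression matrix")
    values = tpm.data.loc[present].to_numpy(dtype=float)
    if tpm.layer.startswith("log"):
        logged = values  # already log2(x + 1)
        linear = np.exp2(values) - 1.0
    else:
        logged = np.log2(values + 1.0)
        linear = values
    if mode == "sum_of_logs":
        total = logged.sum(axis=0)
    elif mode == "log_of_sum":
        total = np.log2(linear.sum(axis=0) + 1.0)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    return pd.Series(total, index=tpm.data.columns, name="cumulative_adnp")


def per_region_aging_scan(
    tpm: GeneExpressionMatrix,
    meta: pd.DataFrame,
    adnp_list: GeneList,
    np_list: GeneList | None = None,
    min_n: int = 20,
    alpha: float = 0.05,
    already_filtered: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partial Spearman (age vs cumulative ADNP, adjusting RIN + Hardy) per region.

    Returns a per-region table (region, n, partial_rho, p_value,
    significant) and, when ``np_list`` is given, a per-gene table of
    partial correlations for every NP gene present.  Regions below
    ``min_n`` retained samples are skipped with a warning.
    """
    if already_filtered:
        kept = meta
    else:
        kept, _ = filter_aging_samples(meta)
    kept = kept.loc[[s for s in kept.index if s in set(tpm.obs_ids)]]
    cumulative = cumulative_adnp_expression(tpm, adnp_list)

    region_rows = []
    gene_rows = []
    gene_set = {normalize_symbol(g) for g in tpm.gene_ids}
    np_genes = [s for s in (np_list.symbols if np_list else []) if s in gene_set]
    for region, group in kept.groupby("region", sort=True):
        n = len(group)
        if n < min_n:
            logger.warning("per_region_aging_scan: region %s has %d < %d samples, skipped",
                           region, n, min_n)
            continue
        ids = list(group.index)
        age = np.array([age_to_numeric(a) for a in group["age"]])
        covariates = np.column_stack([
            pd.to_numeric(group["rin"]).to_numpy(dtype=float),
            pd.to_numeric(group["hardy"]).to_numpy(dtype=float),
        ])
        result = partial_spearman(cumulative.loc[ids].to_numpy(), age, covariates)
        region_rows.append({
            "region": region, "n": n, "partial_rho": result.estimate,
            "p_value": result.p_value, "significant": result.p_value < alpha,
        })
        sub = tpm.data.loc[np_genes, ids] if np_genes else None
        for gene in np_genes:
            expr = sub.loc[gene].to_numpy(dtype=float)
            if tpm.layer.startswith("log"):
                y = expr
            else:
                y = np.log2(expr + 1.0)
            if np.ptp(y) == 0:
                continue
            r = partial_spearman(y, age, covariates)
            gene_rows.append({
                "region": region, "gene": gene, "partial_rho": r.estimate,
                "p_value": r.p_value, "significant": r.p_value < alpha,
            })
    if not region_rows:
        raise ValidationError(f"no region meets the minimum sample count ({min_n})")
    region_table = pd.DataFrame(region_rows)
    gene_table = pd.DataFrame(gene_rows, columns=["region", "gene", "partial_rho", "p_value", "significant"])
    return region_table, gene_table
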