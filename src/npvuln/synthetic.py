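"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators produce desk-scale stand-ins for the study designs
the pipeline targets, each a pure function of its parameter object
(seed included), so identical parameters give identical bytes:

* a single-cell cohort whose per-cell NP co-expression counts follow a
  zero-inflated truncated geometric (a long right tail over a large
  zero mass, as brain snRNA-seq shows), with per-NP expression means
  coupled to the count so that count and summed NP abundance are
  strongly rank-correlated, and with a condition-dependent depletion
  of high-co-expression cells implemented by resampling high counts
  downward (per-donor cell totals stay fixed, isolating the
  proportion signal);
* a bulk aging cohort in which designated regions carry a monotone
  age decline of cumulative ADNP expression with RIN/Hardy covariates,
  plus planted exclusion-filter violators;
* a cluster annotation table with planted AHNP clusters hitting exact
  per-region cell totals and boundary decoys that each violate exactly
  one AHNP criterion.

Every generator returns a truth record sufficient to score the
downstream stage without re-deriving ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log

import numpy as np
import pandas as pd

from .io import GeneExpressionMatrix, GeneList, ValidationError

HIGH_THRESHOLD = 6  # np_count at and above which a cell is "high"


def _default_np_panel() -> GeneList:
    adnp = [f"ADNP{i:02d}" for i in range(1, 12)]
    other = [f"NP{i:03d}" for i in range(12, 101)]
    return GeneList("synthetic-np-panel", adnp + other)


def _default_adnp() -> GeneList:
    return GeneList("synthetic-adnp", [f"ADNP{i:02d}" for i in range(1, 12)])


def _default_planted_deg() -> dict[str, float]:
    up = {f"BG{i:03d}": log(2.0) for i in range(1, 6)}
    down = {f"BG{i:03d}": -log(2.0) for i in range(6, 11)}
    return {**up, **down}


@dataclass
class SCGeneratorParams:
    """Defaults mirror the study design: 8 donors per condition, >=5,000 cells,
    100-NP panel with 11 ADNPs, ~50% zero-NP cells, and a 2-fold planted
    expression effect on ten background genes."""

    n_donors_per_condition: int = 8
    cells_per_donor: int = 600
    conditions: tuple[str, ...] = ("CT", "AD")
    affected_conditions: tuple[str, ...] = ("AD",)
    np_panel: GeneList = field(default_factory=_default_np_panel)
    adnp_subset: GeneList = field(default_factory=_default_adnp)
    background_genes: int = 200
    zero_np_fraction: float = 0.5
    np_count_tail: float = 0.35
    coupling: float = 1.0
    base_expression: float = 2.0
    nb_dispersion: float = 2.0
    adnp_weight: float = 5.0
    hnp_depletion: float = 0.5
    planted_deg: dict[str, float] = field(default_factory=_default_planted_deg)
    seed: int = 0

    def __post_init__(self) -> None:
        if not set(self.adnp_subset.symbols) <= set(self.np_panel.symbols):
            raise ValidationError("adnp_subset must be a subset of np_panel")
        for name in ("zero_np_fraction", "hnp_depletion"):
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ValidationError(f"{name} must be a fraction in [0, 1]")
        if not (0 < self.np_count_tail < 1):
            raise ValidationError("np_count_tail must lie in (0, 1)")
        if self.coupling <= 0:
            raise ValidationError("coupling must be positive")
        unaffected = set(self.affected_conditions) - set(self.conditions)
        if unaffected:
            raise ValidationError(f"affected conditions not in conditions: {sorted(unaffected)}")


def _count_probabilities(params: SCGeneratorParams) -> np.ndarray:
    """P(np_count = c) for c = 0..panel size: zero mass + truncated geometric tail."""
    size = len(params.np_panel)
    c = np.arange(1, size + 1)
    tail = params.np_count_tail * (1 - params.np_count_tail) ** (c - 1)
    tail = tail / tail.sum() * (1 - params.zero_np_fraction)
    return np.concatenate([[params.zero_np_fraction], tail])


def simulate_np_counts(params: SCGeneratorParams, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Fast path: per-cell np_count with donor/condition metadata, no expression matrix.

    Stratification and the stratum-proportion comparison depend only on
    these counts, so power and type-I simulations use this path.
    Depletion resamples high counts (>= 6) from the conditional low/mid
    distribution with probability ``hnp_depletion`` in affected
    conditions, keeping per-donor cell totals fixed.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    probs = _count_probabilities(params)
    low_mid = probs[:HIGH_THRESHOLD] / probs[:HIGH_THRESHOLD].sum()
    rows = []
    for condition in params.conditions:
        for d in range(params.n_donors_per_condition):
            donor = f"{condition}_donor{d + 1:02d}"
            counts = rng.choice(len(probs), size=params.cells_per_donor, p=probs)
            if condition in params.affected_conditions and params.hnp_depletion > 0:
                high = counts >= HIGH_THRESHOLD
                resample = high & (rng.random(params.cells_per_donor) < params.hnp_depletion)
                counts[resample] = rng.choice(HIGH_THRESHOLD, size=int(resample.sum()), p=low_mid)
            for i, c in enumerate(counts):
                rows.append((f"{donor}_cell{i + 1:04d}", donor, condition, int(c)))
    return pd.DataFrame(rows, columns=["obs_id", "donor_id", "condition", "np_count"]).set_index("obs_id")


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def generate_sc_dataset(params: SCGeneratorParams):
    """Full single-cell cohort: raw counts matrix, per-cell metadata, truth record.

    Per cell, ``np_count`` distinct NP genes are expressed (ADNP-weighted
    selection for high cells); each expressed NP draws 1 + NB counts
    with mean proportional to (1 + coupling * np_count), so transcript
    sum tracks the count.  Background genes are negative binomial with
    planted condition effects from ``planted_deg``.
    """
    rng = np.random.default_rng(params.seed)
    cells = simulate_np_counts(params, rng)
    n_cells = len(cells)
    np_genes = list(params.np_panel.symbols)
    n_np = len(np_genes)
    if cells["np_count"].max() > n_np:
        raise ValidationError("np_panel smaller than the maximum achievable np_count")
    bg_genes = sorted(set([f"BG{i:03d}" for i in range(1, params.background_genes + 1)])
                      | set(params.planted_deg))
    mt_genes = ["MT-ND1", "MT-ND2", "MT-CO1"]

    # NP selection by Gumbel top-k: per-cell weights favor ADNPs for high cells
    adnp_mask = np.array([g in set(params.adnp_subset.symbols) for g in np_genes])
    counts_arr = cells["np_count"].to_numpy()
    log_w = np.zeros((n_cells, n_np))
    log_w[counts_arr >= HIGH_THRESHOLD] = np.where(adnp_mask, np.log(params.adnp_weight), 0.0)
    gumbel = rng.gumbel(size=(n_cells, n_np))
    order = np.argsort(-(log_w + gumbel), axis=1)
    chosen = np.zeros((n_cells, n_np), dtype=bool)
    rows = np.repeat(np.arange(n_cells), counts_arr)
    cols = np.concatenate([order[i, :c] for i, c in enumerate(counts_arr)]) if counts_arr.sum() else np.array([], int)
    chosen[rows, cols] = True

    mu = params.base_expression * (1.0 + params.coupling * counts_arr)
    np_values = np.zeros((n_cells, n_np), dtype=np.int64)
    mu_cells = np.broadcast_to(mu[:, None], (n_cells, n_np))[chosen]
    np_values[chosen] = 1 + _negative_binomial(rng, np.maximum(mu_cells - 1.0, 0.05), params.nb_dispersion)

    base_means = rng.uniform(0.5, 5.0, size=len(bg_genes))
    affected = cells["condition"].isin(params.affected_conditions).to_numpy()
    lfc = np.array([params.planted_deg.get(g, 0.0) for g in bg_genes])
    bg_mu = base_means[None, :] * np.where(affected[:, None], np.exp(lfc)[None, :], 1.0)
    bg_values = _negative_binomial(rng, bg_mu, params.nb_dispersion)

    mt_values = rng.poisson(1.0, size=(n_cells, len(mt_genes)))

    data = np.concatenate([np_values, bg_values, mt_values], axis=1).T  # genes x cells
    genes = np_genes + bg_genes + mt_genes
    matrix = GeneExpressionMatrix(
        pd.DataFrame(data, index=genes, columns=cells.index), "raw_counts"
    )
    totals = data.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_mito = np.where(totals > 0, data[len(genes) - len(mt_genes):].sum(axis=0) / totals, 0.0)
    meta = pd.DataFrame({
        "donor_id": cells["donor_id"],
        "condition": cells["condition"],
        "pct_mito": pct_mito,
    }, index=cells.index)
    stratum = np.where(counts_arr <= 1, "low", np.where(counts_arr <= 5, "mid", "high"))
    truth = {
        "np_count": cells["np_count"].copy(),
        "stratum": pd.Series(stratum, index=cells.index),
        "planted_deg": dict(params.planted_deg),
        "np_panel": list(np_genes),
        "adnp": list(params.adnp_subset.symbols),
        "background_genes": bg_genes,
    }
    return matrix, meta, truth


# ---------------------------------------------------------------------------
# bulk aging cohort


@dataclass
class AgingGeneratorParams:
    """Defaults target a population partial rho of about -0.35 in decline
    regions at n = 103 (0.04 log2-units lost per year on the cumulative
    scale against per-gene noise of 0.45)."""

    regions: tuple[tuple[str, str], ...] = (
        ("Hippocampus", "decline"),
        ("Frontal cortex (BA9)", "decline"),
        ("Hypothalamus", "null"),
        ("Cerebellum", "null"),
    )
    n_per_region: int = 103
    age_range: tuple[int, int] = (30, 79)
    decline_slope: float = -0.04
    noise_sd: float = 0.45
    rin_range: tuple[float, float] = (6.1, 9.8)
    hardy_probs: dict[int, float] = field(default_factory=lambda: {0: 0.25, 1: 0.40, 2: 0.35})
    covariate_confounding: float = 0.0
    violation_fraction: float = 0.06
    adnp_list: GeneList = field(default_factory=_default_adnp)
    n_other_np: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (20 <= self.age_range[0] <= self.age_range[1] <= 110):
            raise ValidationError("age_range must lie within [20, 110]")
        if abs(sum(self.hardy_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("hardy_probs must sum to 1")
        for trend in {t for _, t in self.regions}:
            if trend not in ("decline", "null"):
                raise ValidationError(f"unknown region trend {trend!r}")


def generate_aging_cohort(params: AgingGeneratorParams):
    """Bulk TPM cohort with planted age declines: (tpm matrix, metadata, truth)."""
    rng = np.random.default_rng(params.seed)
    adnp = list(params.adnp_list.symbols)
    other_np = [f"NP{i:03d}" for i in range(12, 12 + params.n_other_np)]
    genes = adnp + other_np
    intercepts = rng.uniform(3.0, 6.0, size=len(genes))
    slope_share = params.decline_slope / len(adnp)
    hardy_levels = np.array(sorted(params.hardy_probs))
    hardy_p = np.array([params.hardy_probs[h] for h in hardy_levels])

    sample_rows = []
    columns = {}
    violators: dict[str, list[str]] = {"incomplete": [], "hardy": [], "rin": [], "age": []}

    def _expression(region_trend: str, age: float) -> np.ndarray:
        logtpm = intercepts.copy()
        if region_trend == "decline":
            logtpm[: len(adnp)] = logtpm[: len(adnp)] + slope_share * age
        logtpm = logtpm + rng.normal(0.0, params.noise_sd, size=len(genes))
        return np.maximum(np.exp2(logtpm) - 1.0, 0.0)

    counter = 0
    for region, trend in params.regions:
        n_viol = int(round(params.violation_fraction * params.n_per_region))
        specs = [("ok", params.n_per_region)] + [(kind, n_viol) for kind in violators]
        for kind, n in specs:
            for _ in range(n):
                counter += 1
                sid = f"S{counter:04d}"
                age = float(rng.integers(params.age_range[0], params.age_range[1] + 1))
                rin = float(rng.uniform(*params.rin_range))
                if params.covariate_confounding:
                    mid = (params.age_range[0] + params.age_range[1]) / 2.0
                    spread = (params.age_range[1] - params.age_range[0]) / 4.0
                    rin = float(np.clip(rin - params.covariate_confounding * (age - mid) / spread, 1.0, 10.0))
                hardy = int(rng.choice(hardy_levels, p=hardy_p))
                sex = "male" if rng.random() < 0.5 else "female"
                if kind == "incomplete":
                    sex = pd.NA
                elif kind == "hardy":
                    hardy = int(rng.choice([3, 4]))
                elif kind == "rin":
                    rin = float(rng.uniform(3.0, 6.0))
                elif kind == "age":
                    age = float(rng.integers(20, 30))
                if kind != "ok":
                    violators[kind].append(sid)
                columns[sid] = _expression(trend, age)
                sample_rows.append({"sample_id": sid, "region": region, "age": age,
                                    "sex": sex, "hardy": hardy, "rin": rin})
    tpm = GeneExpressionMatrix(
        pd.DataFrame(columns, index=genes), "tpm"
    )
    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    truth = {
        "region_trends": dict(params.regions),
        "violators": violators,
        "decline_slope": params.decline_slope,
        "adnp": adnp,
        "np": adnp + other_np,
    }
    return tpm, meta, truth


# ---------------------------------------------------------------------------
# cluster annotation tables


def _default_regions() -> dict[str, list[str]]:
    return {
        "Cerebral cortex": ["MEC", "LEC", "MTG", "M1C", "A40"],
        "Amygdala": ["CEN", "BLN"],
        "Basal forebrain": ["NDB", "SI"],
        "Hippocampus": ["CA1", "DG"],
        "Hypothalamus": ["MN", "LZ"],
        "Cerebellum": ["CBV"],
    }


def _default_planted() -> dict[str, int]:
    # scaled-down mirror of the reported regional ordering
    return {
        "Cerebral cortex": 21815,
        "Amygdala": 7226,
        "Basal forebrain": 4556,
        "Hippocampus": 4087,
        "Hypothalamus": 2322,
    }


@dataclass
class AnnotationGeneratorParams:
    n_clusters: int = 30
    regions_with_dissections: dict[str, list[str]] = field(default_factory=_default_regions)
    planted_ahnp_regions: dict[str, int] = field(default_factory=_default_planted)
    tag_noise: float = 0.1
    adnp_list: GeneList = field(default_factory=_default_adnp)
    np_panel: GeneList = field(default_factory=_default_np_panel)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.planted_ahnp_regions.values()):
            raise ValidationError("planted totals must be non-negative")
        unknown = set(self.planted_ahnp_regions) - set(self.regions_with_dissections)
        if unknown:
            raise ValidationError(f"planted regions without dissections: {sorted(unknown)}")
        n_planted = 2 * len(self.planted_ahnp_regions)
        if self.n_clusters < n_planted + 3:
            raise ValidationError(
                f"n_clusters={self.n_clusters} cannot hold {n_planted} planted clusters plus decoys"
            )


def generate_cluster_annotation(params: AnnotationGeneratorParams):
    """(annotation records, dissection -> region map, truth record).

    Planted AHNP clusters hit each region's target cell total exactly
    (two clusters per region, integer cell splits over that region's
    dissections).  Three boundary decoys probe the classification rule:
    exactly (6 ADNP, 2 non-ADNP) -> true, (6, 3) -> false, (5, 0) ->
    false.  Remaining clusters are low-tag background.
    """
    from .regional import ClusterAnnotationRecord  # local import avoids a cycle

    rng = np.random.default_rng(params.seed)
    adnp = list(params.adnp_list.symbols)
    non_adnp = [g for g in params.np_panel.symbols if g not in set(adnp)]
    region_map = {d: r for r, ds in params.regions_with_dissections.items() for d in ds}
    records: list[ClusterAnnotationRecord] = []
    truth_regions: dict[str, float] = {}
    truth_dissections: dict[str, float] = {}
    ahnp_ids: list[str] = []
    transmitters = ["GABA", "glutamate"]
    subtypes = ["SST", "PVALB", "VIP", "LAMP5"]
    mtg = ["Inh L1-2", "Inh L3-5", "Exc L2-3", "Exc L5-6"]

    def _tags(n_adnp: int, n_non: int) -> set[str]:
        tags = set(rng.choice(adnp, size=n_adnp, replace=False))
        if n_non:
            tags |= set(rng.choice(non_adnp, size=n_non, replace=False))
        if rng.random() < params.tag_noise:
            tags.add("XNP-UNKNOWN")
        return tags

    cluster_no = 0

    def _next_id() -> str:
        nonlocal cluster_no
        cluster_no += 1
        return f"C{cluster_no:03d}"

    for region_idx, (region, total) in enumerate(params.planted_ahnp_regions.items()):
        dissections = params.regions_with_dissections[region]
        split_a = int(round(total * 0.6))
        for part_idx, part_total in enumerate((split_a, total - split_a)):
            if part_total <= 0:
                continue
            cid = _next_id()
            use = list(dissections) if len(dissections) <= 3 else [
                str(d) for d in rng.choice(dissections, size=3, replace=False)]
            shares = rng.dirichlet(np.ones(len(use)) * 4.0)
            cells = np.floor(shares * part_total).astype(int)
            cells[0] += part_total - cells.sum()
            pct = {d: 100.0 * c / part_total for d, c in zip(use, cells) if c > 0}
            if region_idx == 0 and part_idx == 0:
                n_adnp, n_non = 6, 2  # inclusive boundary, classified true
            else:
                n_adnp = int(rng.integers(6, len(adnp) + 1))
                n_non = int(rng.integers(0, 3))
            records.append(ClusterAnnotationRecord(
                cluster_id=cid, np_tags=_tags(n_adnp, n_non), total_cells=part_total,
                dissection_percentages=pct,
                neurotransmitter=str(rng.choice(transmitters, p=[0.75, 0.25])),
                subtype=str(rng.choice(subtypes)),
                mtg_label=str(rng.choice(mtg)) if rng.random() < 0.75 else None,
            ))
            ahnp_ids.append(cid)
            truth_regions[region] = truth_regions.get(region, 0) + part_total
            for d, c in zip(use, cells):
                if c > 0:
                    truth_dissections[d] = truth_dissections.get(d, 0) + c

    decoys = {}
    decoy_specs = [("6_3", 6, 3, False), ("5_0", 5, 0, False)]
    all_dissections = sorted(region_map)
    for name, n_adnp, n_non, _is in decoy_specs:
        cid = _next_id()
        d = str(rng.choice(all_dissections))
        records.append(ClusterAnnotationRecord(
            cluster_id=cid, np_tags=_tags(n_adnp, n_non), total_cells=int(rng.integers(500, 3000)),
            dissection_percentages={d: 100.0},
            neurotransmitter="GABA", subtype=str(rng.choice(subtypes)),
        ))
        decoys[name] = cid
    decoys["6_2"] = records[0].cluster_id  # the inclusive-boundary planted cluster

    while cluster_no < params.n_clusters:
        cid = _next_id()
        use = [str(d) for d in rng.choice(all_dissections, size=2, replace=False)]
        shares = [60.0, 30.0]  # 90% sum: exercises the shortfall path
        records.append(ClusterAnnotationRecord(
            cluster_id=cid,
            np_tags=_tags(int(rng.integers(0, 4)), int(rng.integers(3, 7))),
            total_cells=int(rng.integers(200, 2000)),
            dissection_percentages=dict(zip(use, shares)),
            neurotransmitter=str(rng.choice(transmitters)),
            subtype=str(rng.choice(subtypes)),
        ))

    truth = {
        "per_region": truth_regions,
        "per_dissection": truth_dissections,
        "ahnp_clusters": ahnp_ids,
        "decoys": decoys,
        "ranking": [r for r, _ in sorted(truth_regions.items(), key=lambda kv: (-kv[1], kv[0]))],
    }
    return records, region_map, truth
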