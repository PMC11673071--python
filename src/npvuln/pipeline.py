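"""Orchestration of the three analyses: function, time, and space.

The function analysis scores a single-cell cohort (QC, CPM, log,
co-expression counting, stratification), correlates count with NP
abundance, compares donor-level stratum proportions, runs the two DGE
contrasts (high vs low within control; mid control vs mid affected),
regresses expression on NP count, and closes with the hypergeometric
overlap of HNP-elevated and AD-decreased genes.  The time analysis
compares stratum proportions across conditions with one-tailed
rank-sum tests and/or runs the per-region aging scan.  The space
analysis classifies AHNP clusters and estimates regional abundance.

Every run writes its result files plus a machine-readable JSON report
(stage tallies, file list, config echo); all randomness flows from the
config seed, so identical config + inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .aging import per_region_aging_scan
from .diffexp import DGEFilter, np_count_regression, rank_regression_hits, wilcoxon_dge
from .overlap import build_overlap_input, hypergeom_overlap_test
from .profiling import (
    QCThresholds,
    StratumScheme,
    compare_stratum_proportions,
    count_np_coexpression,
    cpm_normalize,
    log_transform,
    np_count_abundance_correlation,
    qc_filter,
    stratify,
    stratum_proportions,
)
from .regional import (
    AHNPCriteria,
    dissection_membership_breakdown,
    estimate_regional_counts,
    rank_top_regions,
    read_cluster_annotation,
    read_region_map,
    round_half_up,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # single-cell inputs
    matrix: str | None = None
    features: str | None = None
    barcodes: str | None = None
    dense_matrix: str | None = None
    meta: str | None = None
    np_list: str | None = None
    adnp_list: str | None = None
    # bulk inputs
    tpm: str | None = None
    bulk_meta: str | None = None
    # annotation inputs
    annotation: str | None = None
    region_map: str | None = None
    breakdown_dissection: str | None = None
    # analysis parameters
    control_condition: str = "CT"
    affected_conditions: tuple[str, ...] = ("AD",)
    scheme: StratumScheme = field(default_factory=StratumScheme)
    qc: QCThresholds = field(default_factory=QCThresholds)
    dge_filter: DGEFilter = field(default_factory=DGEFilter)
    ahnp: AHNPCriteria = field(default_factory=AHNPCriteria)
    alpha: float = 0.05
    top_k: int = 5
    seed: int = 0
    out_dir: str = "npvuln_out"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise io.ValidationError("alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key, klass in (("scheme", StratumScheme), ("qc", QCThresholds),
                           ("dge_filter", DGEFilter), ("ahnp", AHNPCriteria)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        if "affected_conditions" in raw:
            raw["affected_conditions"] = tuple(raw["affected_conditions"])
        return cls(**raw)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class RunReport:
    analysis: str
    config: dict
    version: str = __version__
    tallies: dict = field(default_factory=dict)
    result_files: list = field(default_factory=list)
    skipped: list = field(default_factory=list)
    wall_clock: dict = field(default_factory=dict)

    def write(self, path) -> None:
        io.write_json(dataclasses.asdict(self), path)


class _Stage:
    """Times a pipeline stage and records it in the report."""

    def __init__(self, report: RunReport, name: str):
        self.report, self.name = report, name

    def __enter__(self):
        self.start = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report.wall_clock[self.name] = time.perf_counter() - self.start
        if exc is not None:
            logger.error("stage %s: failed: %s", self.name, exc)
        return False


def _load_sc_inputs(config: RunConfig):
    if config.dense_matrix:
        matrix = io.read_dense_table(config.dense_matrix, layer="raw_counts")
    elif config.matrix:
        matrix = io.read_matrix_market(config.matrix, config.features, config.barcodes)
    else:
        raise io.ValidationError("single-cell analysis needs matrix+features+barcodes or dense_matrix")
    meta = io.read_metadata_table(config.meta)
    np_list = io.read_gene_list(config.np_list, "NP")
    adnp_list = io.read_gene_list(config.adnp_list, "ADNP") if config.adnp_list else None
    return matrix, meta, np_list, adnp_list


def _profile(matrix, meta, np_list, config, report):
    with _Stage(report, "qc"):
        filtered, tally = qc_filter(matrix, meta, config.qc)
        report.tallies["qc"] = tally
    with _Stage(report, "normalize"):
        cpm = cpm_normalize(filtered)
        logged = log_transform(cpm)
    with _Stage(report, "profile"):
        profiles = count_np_coexpression(logged, np_list, presence_matrix=filtered)
        profiles = stratify(profiles, config.scheme)
    return filtered, logged, profiles


def run_function_analysis(config: RunConfig) -> RunReport:
    """QC -> CPM -> log -> count -> stratify -> correlation -> proportions -> DGE -> regression -> overlap."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport("function", config.echo())
    matrix, meta, np_list, _ = _load_sc_inputs(config)
    filtered, logged, profiles = _profile(matrix, meta, np_list, config, report)

    def _emit(name):
        report.result_files.append(str(out / name))
        return out / name

    profiles.to_csv(_emit("profiles.tsv"), sep="\t")

    with _Stage(report, "correlation"):
        corr = np_count_abundance_correlation(profiles)
        io.write_json(dataclasses.asdict(corr), _emit("correlation.json"))

    with _Stage(report, "proportions"):
        props = stratum_proportions(profiles, meta)
        io.write_results_table(props.to_dict("records"), _emit("proportions.tsv"), "proportions")

    conditions = meta["condition"].reindex(profiles.index)
    control = conditions == config.control_condition
    affected = conditions.isin(config.affected_conditions)

    contrasts = {
        "dge_high_vs_low_control.tsv": (
            profiles.index[control & (profiles["stratum"] == "high")],
            profiles.index[control & (profiles["stratum"] == "low")],
        ),
        "dge_mid_control_vs_affected.tsv": (
            profiles.index[control & (profiles["stratum"] == "mid")],
            profiles.index[affected & (profiles["stratum"] == "mid")],
        ),
    }
    dge_results = {}
    with _Stage(report, "dge"):
        for name, (a_ids, b_ids) in contrasts.items():
            if len(a_ids) == 0 or len(b_ids) == 0:
                reason = f"{name}: a contrast group is empty, skipped"
                logger.warning(reason)
                report.skipped.append(reason)
                continue
            result = wilcoxon_dge(logged, list(a_ids), list(b_ids), config.dge_filter)
            dge_results[name] = result
            io.write_results_table(result.to_dict("records"), _emit(name), "dge")
            report.tallies[name] = {"genes_tested": len(result),
                                    "significant": int((result["fdr"] < config.alpha).sum())}

    with _Stage(report, "regression"):
        hnp = dge_results.get("dge_high_vs_low_control.tsv")
        if hnp is not None and len(hnp):
            increased = hnp.loc[(hnp["fdr"] < config.alpha) & (hnp["log_fc"] > 0), "gene"]
            subset = list(increased) if len(increased) >= 3 else None
            regression = np_count_regression(logged, profiles, subset)
            io.write_results_table(regression.to_dict("records"), _emit("regression.tsv"), "regression")
            top_coef, top_r2 = rank_regression_hits(regression)
            report.tallies["regression"] = {"genes": len(regression),
                                            "top_by_coefficient": top_coef, "top_by_r2": top_r2}
        else:
            report.skipped.append("regression: no high-vs-low DGE results to regress")

    with _Stage(report, "overlap"):
        hnp = dge_results.get("dge_high_vs_low_control.tsv")
        mnp = dge_results.get("dge_mid_control_vs_affected.tsv")
        if hnp is not None and mnp is not None:
            hnp_up = set(hnp.loc[(hnp["fdr"] < config.alpha) & (hnp["log_fc"] > 0), "gene"])
            # contrast is control(mid) over affected(mid): decreased in affected means log_fc > 0
            ad_down = set(mnp.loc[(mnp["fdr"] < config.alpha) & (mnp["log_fc"] > 0), "gene"])
            universe = set(logged.gene_ids)
            if hnp_up and ad_down:
                inp = build_overlap_input(hnp_up, ad_down, universe)
                result = hypergeom_overlap_test(inp)
                io.write_json({
                    "x": inp.x, "m": inp.m, "n": inp.n, "k": inp.k,
                    "p_value": result.p_value, "expected_overlap": result.expected_overlap,
                    "fold_enrichment": result.fold_enrichment,
                }, _emit("overlap.json"))
            else:
                report.skipped.append("overlap: a DGE gene set is empty")
        else:
            report.skipped.append("overlap: missing a DGE contrast")

    report.write(out / "report_function.json")
    return report


def run_time_analysis(config: RunConfig) -> RunReport:
    """Condition-wise stratum proportion tests and/or the per-region aging scan."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport("time", config.echo())

    if config.matrix or config.dense_matrix:
        matrix, meta, np_list, adnp_list = _load_sc_inputs(config)
        score_list = adnp_list or np_list
        _, _, profiles = _profile(matrix, meta, score_list, config, report)
        with _Stage(report, "proportions"):
            props = stratum_proportions(profiles, meta)
            path = out / "proportions.tsv"
            io.write_results_table(props.to_dict("records"), path, "proportions")
            report.result_files.append(str(path))
        with _Stage(report, "stratum_tests"):
            rows = []
            for condition in config.affected_conditions:
                if condition not in set(props["condition"]):
                    raise io.ValidationError(f"condition {condition!r} missing from metadata")
                for stratum, alternative in (("high", "greater"), ("low", "less")):
                    res = compare_stratum_proportions(
                        props, config.control_condition, condition, stratum, alternative)
                    rows.append({
                        "statistic_name": f"{config.control_condition}_vs_{condition}_{stratum}",
                        "estimate": res.estimate, "p_value": res.p_value,
                        "n": res.n, "alternative": res.alternative,
                    })
            path = out / "stratum_tests.tsv"
            io.write_results_table(rows, path, "association")
            report.result_files.append(str(path))
            report.tallies["stratum_tests"] = {
                "comparisons": len(rows),
                "significant": sum(1 for r in rows if r["p_value"] < config.alpha),
            }

    if config.tpm:
        with _Stage(report, "aging_scan"):
            tpm = io.read_dense_table(config.tpm, layer="tpm")
            bulk_meta = pd.read_csv(config.bulk_meta, sep="\t", index_col=0)
            adnp = io.read_gene_list(config.adnp_list, "ADNP")
            np_genes = io.read_gene_list(config.np_list, "NP") if config.np_list else None
            regions, genes = per_region_aging_scan(tpm, bulk_meta, adnp, np_genes, alpha=config.alpha)
            path = out / "aging_regions.tsv"
            io.write_results_table(regions.to_dict("records"), path, "aging")
            report.result_files.append(str(path))
            if len(genes):
                gpath = out / "aging_genes.tsv"
                genes.to_csv(gpath, sep="\t", index=False)
                report.result_files.append(str(gpath))
            report.tallies["aging_scan"] = {
                "regions": len(regions),
                "significant": int(regions["significant"].sum()),
            }

    if not report.result_files:
        raise io.ValidationError("time analysis needs single-cell and/or bulk inputs")
    report.write(out / "report_time.json")
    return report


def run_space_analysis(config: RunConfig) -> RunReport:
    """AHNP classification, regional/dissection abundance, top-k ranking, optional breakdown."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport("space", config.echo())
    if not config.annotation:
        raise io.ValidationError("space analysis needs an annotation table")
    if not config.region_map:
        raise io.ValidationError("space analysis needs a dissection -> region map")
    records = read_cluster_annotation(config.annotation)
    region_map = read_region_map(config.region_map)
    adnp = io.read_gene_list(config.adnp_list, "ADNP")
    np_genes = io.read_gene_list(config.np_list, "NP")

    with _Stage(report, "estimate"):
        for level, name in (("region", "regional_counts.tsv"), ("dissection", "dissection_counts.tsv")):
            table = estimate_regional_counts(records, adnp, np_genes, config.ahnp,
                                             region_map, level=level)
            rounded = table.copy()
            rounded["ahnp_cell_estimate"] = rounded["ahnp_cell_estimate"].map(round_half_up)
            path = out / name
            io.write_results_table(rounded.to_dict("records"), path, "regional")
            report.result_files.append(str(path))
            top = rank_top_regions(rounded, config.top_k)
            top_path = out / f"top_{level}.tsv"
            io.write_results_table(top.to_dict("records"), top_path, "regional")
            report.result_files.append(str(top_path))
            report.tallies[level] = {"units": len(table)}

    if config.breakdown_dissection:
        with _Stage(report, "breakdown"):
            for attr in ("neurotransmitter", "subtype", "mtg_label"):
                grouped = dissection_membership_breakdown(
                    records, config.breakdown_dissection, adnp, np_genes, config.ahnp,
                    group_by=attr)
                path = out / f"breakdown_{attr}.tsv"
                grouped.to_csv(path, sep="\t", index=False)
                report.result_files.append(str(path))

    report.write(out / "report_space.json")
    return report
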