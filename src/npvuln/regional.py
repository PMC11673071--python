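"""Regional abundance of high-ADNP neuronal clusters from atlas annotations.

A brain atlas annotation table tags each clustered neuronal
subpopulation with its co-expressed neuropeptides and records how the
cluster's cells distribute (as percentages) over microdissected
anatomical units.  Clusters tagged with at least 6 AD-associated
neuropeptides (ADNPs) and strictly fewer than 3 other neuropeptides
are classified AHNP; their cells are attributed to dissections
proportionally and summed per dissection or per region, which is how
regional AHNP abundance is estimated without re-clustering the atlas.

Percentage shortfalls (< 100%) are not renormalized: the residual
plausibly lies in unlisted dissections, and renormalizing would
inflate the listed ones.  Estimates stay real-valued internally and
are rounded half-up only at report time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .io import GeneList, ValidationError, normalize_symbol

logger = logging.getLogger(__name__)

PCT_TOLERANCE = 1e-6


@dataclass
class ClusterAnnotationRecord:
    cluster_id: str
    np_tags: set[str]
    total_cells: int
    dissection_percentages: dict[str, float] = field(default_factory=dict)
    neurotransmitter: str | None = None
    subtype: str | None = None
    mtg_label: str | None = None

    def __post_init__(self) -> None:
        self.np_tags = {normalize_symbol(t) for t in self.np_tags if str(t).strip()}
        if self.total_cells < 0:
            raise ValidationError(f"cluster {self.cluster_id}: negative total_cells")
        for dissection, pct in self.dissection_percentages.items():
            if pct < 0 or pct > 100 + PCT_TOLERANCE:
                raise ValidationError(
                    f"cluster {self.cluster_id}: percentage {pct} for {dissection} outside [0, 100]"
                )

    @property
    def percentage_sum(self) -> float:
        return float(sum(self.dissection_percentages.values()))


@dataclass
class AHNPCriteria:
    """AHNP rule: >= min_adnp ADNP tags and strictly fewer than max_non_adnp_exclusive others."""

    min_adnp: int = 6
    max_non_adnp_exclusive: int = 3

    def __post_init__(self) -> None:
        if self.min_adnp < 1 or self.max_non_adnp_exclusive < 1:
            raise ValidationError("min_adnp and max_non_adnp_exclusive must be >= 1")


def split_np_tags(
    record: ClusterAnnotationRecord, adnp_list: GeneList, np_list: GeneList
) -> tuple[int, int]:
    """(ADNP tag count, non-ADNP NP tag count); tags outside the NP universe are logged and excluded."""
    adnp = set(adnp_list.symbols)
    np_universe = set(np_list.symbols)
    unknown = record.np_tags - np_universe
    if unknown:
        logger.info("cluster %s: tags outside the NP universe ignored: %s",
                    record.cluster_id, sorted(unknown))
    adnp_count = len(record.np_tags & adnp)
    non_adnp_count = len(record.np_tags & (np_universe - adnp))
    return adnp_count, non_adnp_count


def classify_ahnp(
    record: ClusterAnnotationRecord,
    criteria: AHNPCriteria,
    adnp_list: GeneList,
    np_list: GeneList,
) -> bool:
    adnp_count, non_adnp_count = split_np_tags(record, adnp_list, np_list)
    return adnp_count >= criteria.min_adnp and non_adnp_count < criteria.max_non_adnp_exclusive


def _attributed_cells(record: ClusterAnnotationRecord) -> dict[str, float]:
    if record.percentage_sum > 100 + PCT_TOLERANCE:
        raise ValidationError(
            f"cluster {record.cluster_id}: dissection percentages sum to {record.percentage_sum:.4f} > 100"
        )
    if record.percentage_sum < 100 - PCT_TOLERANCE:
        logger.info("cluster %s: percentages sum to %.2f%%; shortfall left unattributed",
                    record.cluster_id, record.percentage_sum)
    return {d: record.total_cells * pct / 100.0 for d, pct in record.dissection_percentages.items()}


def estimate_regional_counts(
    records,
    adnp_list: GeneList,
    np_list: GeneList,
    criteria: AHNPCriteria | None = None,
    region_map: dict[str, str] | None = None,
    level: str = "region",
    only_ahnp: bool = True,
) -> pd.DataFrame:
    """Attribute cluster cells to dissections proportionally and sum per region or dissection.

    Returns a DataFrame (region_or_dissection, ahnp_cell_estimate,
    n_contributing_clusters) in descending estimate order with
    alphabetical tie-break.  ``region_map`` (dissection -> region) is
    required at region level.
    """
    criteria = criteria or AHNPCriteria()
    if level not in ("region", "dissection"):
        raise ValidationError("level must be 'region' or 'dissection'")
    if level == "region" and region_map is None:
        raise ValidationError("region-level estimates need a dissection -> region map")
    totals: dict[str, float] = {}
    contributors: dict[str, set[str]] = {}
    for record in records:
        if only_ahnp and not classify_ahnp(record, criteria, adnp_list, np_list):
            continue
        for dissection, cells in _attributed_cells(record).items():
            if level == "region":
                if dissection not in region_map:
                    raise ValidationError(f"dissection {dissection!r} missing from region map")
                key = region_map[dissection]
            else:
                key = dissection
            totals[key] = totals.get(key, 0.0) + cells
            contributors.setdefault(key, set()).add(record.cluster_id)
    rows = [
        {"region_or_dissection": key, "ahnp_cell_estimate": est,
         "n_contributing_clusters": len(contributors[key])}
        for key, est in totals.items()
    ]
    out = pd.DataFrame(rows, columns=["region_or_dissection", "ahnp_cell_estimate", "n_contributing_clusters"])
    if len(out):
        out = out.sort_values(["ahnp_cell_estimate", "region_or_dissection"],
                              ascending=[False, True], kind="mergesort").reset_index(drop=True)
    return out


def round_half_up(value: float) -> int:
    """Report-time rounding of cell estimates (0.5 always rounds up)."""
    return int(Decimal(repr(float(value))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def rank_top_regions(records: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k rows by estimate (alphabetical tie-break); fewer rows pass through."""
    if records.empty:
        raise ValidationError("no regional records to rank")
    ordered = records.sort_values(["ahnp_cell_estimate", "region_or_dissection"],
                                  ascending=[False, True], kind="mergesort")
    return ordered.head(k).reset_index(drop=True)


def dissection_membership_breakdown(
    records,
    dissection: str,
    adnp_list: GeneList,
    np_list: GeneList,
    criteria: AHNPCriteria | None = None,
    top_n_dissections: int = 3,
    group_by: str = "neurotransmitter",
) -> pd.DataFrame:
    """Cells a target dissection receives from AHNP clusters where it ranks in the top n, grouped by attribute.

    A cluster contributes when the target dissection is among its
    ``top_n_dissections`` largest percentages; its cells attributed to
    that dissection are summed per ``group_by`` label (missing labels
    grouped as 'unannotated').
    """
    criteria = criteria or AHNPCriteria()
    if group_by not in ("neurotransmitter", "subtype", "mtg_label"):
        raise ValidationError("group_by must be neurotransmitter, subtype or mtg_label")
    records = list(records)
    known = sorted({d for r in records for d in r.dissection_percentages})
    if dissection not in known:
        raise ValidationError(f"unknown dissection {dissection!r}; known: {known}")
    sums: dict[str, float] = {}
    for record in records:
        if not classify_ahnp(record, criteria, adnp_list, np_list):
            continue
        if dissection not in record.dissection_percentages:
            continue
        ranked = sorted(record.dissection_percentages.items(), key=lambda kv: (-kv[1], kv[0]))
        top = [d for d, _ in ranked[:top_n_dissections]]
        if dissection not in top:
            continue
        label = getattr(record, group_by) or "unannotated"
        cells = record.total_cells * record.dissection_percentages[dissection] / 100.0
        sums[label] = sums.get(label, 0.0) + cells
    out = pd.DataFrame(
        [{"group": g, "cells": c} for g, c in sums.items()], columns=["group", "cells"]
    )
    if len(out):
        out = out.sort_values(["cells", "group"], ascending=[False, True], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# annotation table I/O (documented schema: see read_cluster_annotation)


def read_cluster_annotation(path) -> list[ClusterAnnotationRecord]:
    """Read a cluster annotation CSV.

    Schema: columns ``cluster_id``, ``np_tags`` (';'-delimited symbols,
    may be empty), ``total_cells``, optional ``neurotransmitter``,
    ``subtype``, ``mtg_label``, plus one ``pct:<dissection>`` column
    per dissection holding percentages in [0, 100].
    """
    frame = pd.read_csv(path)
    required = {"cluster_id", "np_tags", "total_cells"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    pct_cols = [c for c in frame.columns if c.startswith("pct:")]
    records = []
    for _, row in frame.iterrows():
        tags = set() if pd.isna(row["np_tags"]) else {t for t in str(row["np_tags"]).split(";") if t.strip()}
        pcts = {c[len("pct:"):]: float(row[c]) for c in pct_cols if not pd.isna(row[c]) and float(row[c]) > 0}
        records.append(ClusterAnnotationRecord(
            cluster_id=str(row["cluster_id"]),
            np_tags=tags,
            total_cells=int(row["total_cells"]),
            dissection_percentages=pcts,
            neurotransmitter=None if pd.isna(row.get("neurotransmitter")) else str(row["neurotransmitter"]),
            subtype=None if pd.isna(row.get("subtype")) else str(row["subtype"]),
            mtg_label=None if pd.isna(row.get("mtg_label")) else str(row["mtg_label"]),
        ))
    return records


def write_cluster_annotation(records, path) -> None:
    records = list(records)
    dissections = sorted({d for r in records for d in r.dissection_percentages})
    rows = []
    for r in records:
        row = {
            "cluster_id": r.cluster_id,
            "np_tags": ";".join(sorted(r.np_tags)),
            "total_cells": r.total_cells,
            "neurotransmitter": r.neurotransmitter,
            "subtype": r.subtype,
            "mtg_label": r.mtg_label,
        }
        for d in dissections:
            row[f"pct:{d}"] = r.dissection_percentages.get(d, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_region_map(path) -> dict[str, str]:
    """Read a two-column TSV mapping dissection -> region."""
    frame = pd.read_csv(path, sep="\t")
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: expected two columns (dissection, region)")
    return dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(str)))


def write_region_map(region_map: dict[str, str], path) -> None:
    pd.DataFrame(
        {"dissection": list(region_map), "region": [region_map[d] for d in region_map]}
    ).to_csv(path, sep="\t", index=False)
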