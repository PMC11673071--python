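"""File formats and in-memory domain types.

Everything downstream of this module operates on validated in-memory
objects: a genes x observations expression matrix with a layer tag, a
per-observation metadata table, ordered gene lists, and cluster
annotation records.  All readers reject malformed input with an error
that names the offending file coordinates; none silently coerce.

Gene symbols are matched case-insensitively after trimming throughout
the package, because curated neuropeptide lists merged from several
publications use inconsistent casing.  Matrix Market files are 1-based
on disk (per the standard); everything in memory is 0-based.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

LAYERS = ("raw_counts", "cpm", "log_cpm", "tpm", "log_tpm", "log_raw")

CPM_TOTAL = 1e6
CPM_RTOL = 1e-6


class FormatError(ValueError):
    """Malformed external file (bad shape, value or schema)."""


class ValidationError(ValueError):
    """In-memory object violates a domain invariant."""


def normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneExpressionMatrix:
    """Genes x observations non-negative expression table.

    ``data`` is indexed by gene symbol (rows) and observation id
    (columns).  ``layer`` declares the scale of the values.
    ``zero_obs`` flags observations whose raw total was zero and which
    therefore stay all-zero under CPM normalization.
    """

    data: pd.DataFrame
    layer: str = "raw_counts"
    zero_obs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValidationError(f"unknown layer tag {self.layer!r}; expected one of {LAYERS}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate observation ids: {dups}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValidationError("expression values must be finite")
        if (values < 0).any():
            raise ValidationError("expression values must be non-negative")
        if self.layer == "cpm":
            totals = values.sum(axis=0)
            nonzero = totals > 0
            if not np.allclose(totals[nonzero], CPM_TOTAL, rtol=CPM_RTOL):
                raise ValidationError("cpm layer columns must each sum to 1e6")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def obs_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_obs(self) -> int:
        return self.data.shape[1]

    def subset_obs(self, obs_ids) -> "GeneExpressionMatrix":
        missing = [o for o in obs_ids if o not in self.data.columns]
        if missing:
            raise ValidationError(f"unknown observation ids: {missing[:5]}")
        keep = set(obs_ids)
        zero = tuple(o for o in self.zero_obs if o in keep)
        return GeneExpressionMatrix(self.data.loc[:, list(obs_ids)], self.layer, zero)


@dataclass
class GeneList:
    """Named, ordered, unique (after case-normalization) gene symbols."""

    name: str
    symbols: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        normalized: list[str] = []
        seen: set[str] = set()
        dropped = []
        for raw in self.symbols:
            sym = normalize_symbol(raw)
            if not sym:
                continue
            if sym in seen:
                dropped.append(sym)
                continue
            seen.add(sym)
            normalized.append(sym)
        if dropped:
            logger.warning("gene list %s: dropped duplicate symbols %s", self.name, sorted(set(dropped)))
        if not normalized:
            raise ValidationError(f"gene list {self.name!r} is empty")
        self.symbols = normalized

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in set(self.symbols)


METADATA_COLUMNS = ("donor_id", "condition", "braak_stage", "cell_type", "pct_mito")


def validate_metadata(meta: pd.DataFrame, conditions: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Validate a per-observation metadata table (index = obs_id).

    Missing values are pd.NA, never sentinel numbers.  ``conditions``
    optionally declares the allowed condition vocabulary.
    """
    if meta.index.duplicated().any():
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate obs ids in metadata: {dups}")
    if "donor_id" not in meta.columns or "condition" not in meta.columns:
        raise ValidationError("metadata requires donor_id and condition columns")
    if conditions is not None:
        bad = set(meta["condition"].dropna()) - set(conditions)
        if bad:
            raise ValidationError(f"condition labels outside declared vocabulary: {sorted(bad)}")
    if "braak_stage" in meta.columns:
        stages = pd.to_numeric(meta["braak_stage"], errors="coerce").dropna()
        if ((stages < 0) | (stages > 6)).any():
            raise ValidationError("braak_stage must lie in [0, 6]")
    if "pct_mito" in meta.columns:
        frac = pd.to_numeric(meta["pct_mito"], errors="coerce").dropna()
        if ((frac < 0) | (frac > 1)).any():
            raise ValidationError("pct_mito must be a fraction in [0, 1]")
    return meta


# ---------------------------------------------------------------------------
# readers


def _read_lines(path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh]


def read_matrix_market(
    matrix_path,
    features_path,
    barcodes_path,
    orientation: str | None = None,
    on_duplicate: str = "error",
) -> GeneExpressionMatrix:
    """Read a sparse coordinate matrix with feature/barcode sidecar files.

    On-disk orientation is inferred from the sidecar lengths and
    normalized to genes x cells; a square matrix with equally long
    sidecars is ambiguous and requires ``orientation`` ("genes-rows"
    or "genes-cols").  Duplicate feature symbols are a hard error
    unless ``on_duplicate='keep_first'`` is set explicitly: summing
    duplicates would silently change co-expression counts.
    """
    mat = scipy.io.mmread(matrix_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    features = [normalize_symbol(s.split("\t")[0]) for s in _read_lines(features_path) if s.strip()]
    barcodes = [s.split("\t")[0].strip() for s in _read_lines(barcodes_path) if s.strip()]
    n_rows, n_cols = mat.shape

    if orientation is None:
        fits_as_is = (n_rows == len(features) and n_cols == len(barcodes))
        fits_transposed = (n_rows == len(barcodes) and n_cols == len(features))
        if fits_as_is and fits_transposed:
            raise FormatError(
                f"{matrix_path}: orientation is ambiguous ({n_rows}x{n_cols} with "
                f"{len(features)} features and {len(barcodes)} barcodes); pass orientation="
            )
        if fits_as_is:
            orientation = "genes-rows"
        elif fits_transposed:
            orientation = "genes-cols"
        else:
            raise FormatError(
                f"{matrix_path}: matrix is {n_rows}x{n_cols} but sidecars have "
                f"{len(features)} features and {len(barcodes)} barcodes"
            )
    if orientation == "genes-cols":
        mat = mat.T
    elif orientation != "genes-rows":
        raise FormatError(f"unknown orientation {orientation!r}")
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"{matrix_path}: matrix is {mat.shape[0]}x{mat.shape[1]} but sidecars have "
            f"{len(features)} features and {len(barcodes)} barcodes"
        )
    if (mat < 0).any():
        raise ValidationError(f"{matrix_path}: negative entries are not valid counts")

    frame = pd.DataFrame(mat, index=features, columns=barcodes)
    if frame.index.duplicated().any():
        dups = sorted(frame.index[frame.index.duplicated()].unique().tolist())
        if on_duplicate == "keep_first":
            logger.warning("%s: keeping first of duplicate features %s", features_path, dups)
            frame = frame.loc[~frame.index.duplicated(keep="first")]
        else:
            raise FormatError(f"{features_path}: duplicate feature symbols {dups}")
    return GeneExpressionMatrix(frame, "raw_counts")


def write_matrix_market(matrix: GeneExpressionMatrix, matrix_path, features_path, barcodes_path) -> None:
    sparse = scipy.sparse.coo_matrix(matrix.data.to_numpy())
    scipy.io.mmwrite(str(matrix_path), sparse)
    with open(features_path, "w") as fh:
        fh.write("\n".join(matrix.gene_ids) + "\n")
    with open(barcodes_path, "w") as fh:
        fh.write("\n".join(matrix.obs_ids) + "\n")


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_dense_table(path, orientation: str = "genes-rows", layer: str = "tpm") -> GeneExpressionMatrix:
    """Read a delimited expression table (header = obs ids, first column = gene symbols)."""
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    obs = header[1:]
    if len(obs) != len(set(obs)):
        dups = sorted({o for o in obs if obs.count(o) > 1})
        raise FormatError(f"{path}: duplicate header ids {dups}")
    frame = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    frame.index = [normalize_symbol(g) for g in frame.index]
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | frame.isna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        gene, sample = numeric.index[rows[0]], numeric.columns[cols[0]]
        raw = frame.iloc[rows[0], cols[0]]
        raise FormatError(f"{path}: non-numeric cell at gene {gene!r}, column {sample!r}: {raw!r}")
    if orientation == "genes-cols":
        numeric = numeric.T
    elif orientation != "genes-rows":
        raise FormatError(f"unknown orientation {orientation!r}")
    return GeneExpressionMatrix(numeric, layer)


def write_dense_table(matrix: GeneExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep=_sep_for(path), index_label="gene")


def read_gene_list(path, name: str | None = None) -> GeneList:
    """Read a one-symbol-per-line gene list; '#' comments and blanks ignored."""
    symbols = []
    for line in _read_lines(path):
        entry = line.strip()
        if not entry or entry.startswith("#"):
            continue
        symbols.append(entry)
    if not symbols:
        raise FormatError(f"{path}: no gene symbols after filtering comments/blanks")
    return GeneList(name or str(path), symbols)


def write_gene_list(genes: GeneList, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {genes.name}\n")
        fh.write("\n".join(genes.symbols) + "\n")


def read_metadata_table(path, conditions: tuple[str, ...] | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return validate_metadata(meta, conditions)


def write_metadata_table(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep=_sep_for(path), index_label="obs_id")


# ---------------------------------------------------------------------------
# result tables

# schema -> (columns, sort keys, ascending flags)
RESULT_SCHEMAS: dict[str, tuple[list[str], list[str], list[bool]]] = {
    "dge": (
        ["gene", "log_fc", "p_value", "fdr", "pct_a", "pct_b"],
        ["fdr", "p_value", "gene"],
        [True, True, True],
    ),
    "regression": (
        ["gene", "coefficient", "r_squared", "p_value", "fdr"],
        ["fdr", "p_value", "gene"],
        [True, True, True],
    ),
    "association": (
        ["statistic_name", "estimate", "p_value", "n", "alternative"],
        ["statistic_name", "p_value"],
        [True, True],
    ),
    "aging": (
        ["region", "n", "partial_rho", "p_value", "significant"],
        ["p_value", "region"],
        [True, True],
    ),
    "regional": (
        ["region_or_dissection", "ahnp_cell_estimate", "n_contributing_clusters"],
        ["ahnp_cell_estimate", "region_or_dissection"],
        [False, True],
    ),
    "proportions": (
        ["donor_id", "condition", "stratum", "n_cells", "proportion"],
        ["condition", "donor_id", "stratum"],
        [True, True, True],
    ),
}


def _render(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (float, np.floating)):
        return format(float(value), ".6g")
    return str(value)


def write_results_table(records, path, schema_tag: str) -> None:
    """Write records under a declared schema, deterministically sorted, floats at 6 significant digits."""
    if schema_tag not in RESULT_SCHEMAS:
        raise ValidationError(f"unknown result schema {schema_tag!r}; expected one of {sorted(RESULT_SCHEMAS)}")
    columns, keys, ascending = RESULT_SCHEMAS[schema_tag]
    frame = pd.DataFrame(list(records), columns=columns)
    if len(frame):
        frame = frame.sort_values(keys, ascending=ascending, kind="mergesort")
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for _, row in frame.iterrows():
            fh.write("\t".join(_render(row[c]) for c in columns) + "\n")


def read_results_table(path, schema_tag: str) -> pd.DataFrame:
    if schema_tag not in RESULT_SCHEMAS:
        raise ValidationError(f"unknown result schema {schema_tag!r}")
    return pd.read_csv(path, sep="\t")


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
        fh.write("\n")
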