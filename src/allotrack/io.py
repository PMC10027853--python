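"""Readers and writers for every external format the pipeline touches.

Bulk TCRβ repertoires arrive as immunoSEQ-style TSV exports; single-cell
V(D)J data as 10x ``filtered_contig_annotations.csv``; expression as a
MatrixMarket triplet; gene signatures as plain one-gene-per-line lists.
Everything is validated on the way in and converted to a uniform internal
model (dataclasses wrapping pandas/scipy containers).

Frequencies downstream are always computed over *productive templates*:
nonproductive rows are retained in the clone table but never enter a
frequency denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ParseError, ValidationError
from .genes import normalize_gene

logger = logging.getLogger(__name__)

COMPARTMENTS = {"blood", "kidney", "skin", "lymph_node", "mlr", "other"}

#: Accepted header spellings for immunoSEQ-style exports, first match wins.
#: Callers may pass an explicit ``columns`` mapping to override.
BULK_COLUMN_DIALECTS: dict[str, tuple[str, ...]] = {
    "cdr3_nt": ("rearrangement", "nucleotide", "cdr3_rearrangement", "cdr3_nt"),
    "cdr3_aa": ("amino_acid", "aminoAcid", "cdr3_amino_acid", "cdr3_aa"),
    "v_gene": ("v_resolved", "vGeneName", "v_gene"),
    "d_gene": ("d_resolved", "dGeneName", "d_gene"),
    "j_gene": ("j_resolved", "jGeneName", "j_gene"),
    "templates": ("templates", "count (templates/reads)", "count", "template_count"),
    "productive": ("frame_type", "sequenceStatus", "productive"),
}

_TRUE_STRINGS = {"true", "t", "1", "yes"}

CLONE_COLUMNS = ["cdr3_nt", "cdr3_aa", "v_gene", "d_gene", "j_gene", "templates", "productive"]


@dataclass
class BulkRepertoire:
    """One sample's bulk TCRβ clone table plus sample metadata.

    ``clones`` columns: cdr3_nt, cdr3_aa, v_gene, d_gene, j_gene,
    templates (int), productive (bool).  Duplicate (cdr3_nt, v_gene,
    j_gene) rows are aggregated at load time by summing templates.
    """

    sample_id: str
    compartment: str
    timepoint: str
    clones: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r}; expected one of {sorted(COMPARTMENTS)}"
            )
        missing = [c for c in CLONE_COLUMNS if c not in self.clones.columns]
        if missing:
            raise ValidationError(f"clone table missing columns {missing}")

    @property
    def total_templates(self) -> int:
        return int(self.clones["templates"].sum())

    @property
    def productive_templates(self) -> int:
        return int(self.clones.loc[self.clones["productive"], "templates"].sum())

    def productive_clones(self) -> pd.DataFrame:
        return self.clones[self.clones["productive"]]


def _resolve_columns(header: list[str], columns: dict[str, str] | None) -> dict[str, str]:
    """Map canonical clone-table fields to the file's column names."""
    resolved: dict[str, str] = {}
    overrides = columns or {}
    lower = {h.lower(): h for h in header}
    for canon, dialects in BULK_COLUMN_DIALECTS.items():
        if canon in overrides:
            if overrides[canon] not in header:
                raise FormatError(
                    f"configured column {overrides[canon]!r} for field {canon!r} not in header"
                )
            resolved[canon] = overrides[canon]
            continue
        for cand in dialects:
            if cand in header:
                resolved[canon] = cand
                break
            if cand.lower() in lower:
                resolved[canon] = lower[cand.lower()]
                break
    required = ("cdr3_nt", "v_gene", "j_gene", "templates")
    for canon in required:
        if canon not in resolved:
            raise FormatError(
                f"required column for field {canon!r} not found in header {header}; "
                f"accepted names: {BULK_COLUMN_DIALECTS[canon]}"
            )
    return resolved


def _parse_productive(series: pd.Series, source_col: str) -> pd.Series:
    """immunoSEQ encodes productivity as frame_type 'In'/'Out'/'Stop';
    plainer exports use booleans."""
    vals = series.astype(str).str.strip()
    if source_col.lower() in ("frame_type", "sequencestatus"):
        return vals.str.lower().isin(("in", "inframe", "in-frame"))
    out = pd.Series(index=series.index, dtype=bool)
    for i, v in vals.items():
        lv = v.lower()
        if lv in _TRUE_STRINGS:
            out[i] = True
        elif lv in ("false", "f", "0", "no"):
            out[i] = False
        else:
            raise ParseError(f"unparseable productive value {v!r}", row=int(i) + 1)
    return out


def read_bulk_repertoire(
    path: str | Path,
    sample_id: str,
    compartment: str,
    timepoint: str,
    columns: dict[str, str] | None = None,
) -> BulkRepertoire:
    """Load an immunoSEQ-style TSV into a validated :class:`BulkRepertoire`.

    Rows with zero templates are dropped; duplicate (cdr3_nt, v_gene,
    j_gene) rows are aggregated by summing templates; gene names are
    normalized to IMGT spelling with alleles stripped.  Raises
    :class:`FormatError` for a missing required column and
    :class:`ParseError` (with the row number) for a non-integer template
    count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    resolved = _resolve_columns(list(df.columns), columns)

    out = pd.DataFrame(index=df.index)
    out["cdr3_nt"] = df[resolved["cdr3_nt"]].str.strip().str.upper()
    out["cdr3_aa"] = df[resolved["cdr3_aa"]].str.strip() if "cdr3_aa" in resolved else ""
    for g in ("v_gene", "d_gene", "j_gene"):
        if g in resolved:
            out[g] = df[resolved[g]].map(normalize_gene)
        else:
            out[g] = ""

    raw_templates = df[resolved["templates"]].str.strip()
    templates = pd.to_numeric(raw_templates, errors="coerce")
    bad = templates.isna() | (templates != templates.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-integer template count {raw_templates.iloc[row]!r}", row=row + 1
        )
    out["templates"] = templates.astype(int)
    if (out["templates"] < 0).any():
        row = int(np.flatnonzero((out["templates"] < 0).to_numpy())[0])
        raise ParseError("negative template count", row=row + 1)

    if "productive" in resolved:
        out["productive"] = _parse_productive(df[resolved["productive"]], resolved["productive"])
    else:
        out["productive"] = True

    out = out[out["templates"] > 0]
    if (out.loc[out["productive"], "cdr3_nt"] == "").any():
        raise ParseError("productive row with empty CDR3 nucleotide sequence")

    agg = (
        out.groupby(["cdr3_nt", "v_gene", "j_gene"], as_index=False, sort=True)
        .agg(
            cdr3_aa=("cdr3_aa", "first"),
            d_gene=("d_gene", "first"),
            templates=("templates", "sum"),
            productive=("productive", "first"),
        )
    )
    agg = agg[CLONE_COLUMNS].sort_values(
        ["cdr3_nt", "v_gene", "j_gene"], kind="mergesort"
    ).reset_index(drop=True)
    return BulkRepertoire(sample_id, compartment, timepoint, agg)


# ---------------------------------------------------------------------------
# 10x contig annotations

CONTIG_COLUMNS = [
    "barcode", "chain", "v_gene", "j_gene", "cdr3_nt", "cdr3_aa",
    "umis", "reads", "productive", "high_confidence",
]

_CONTIG_SOURCE = {
    "cdr3_nt": "cdr3_nt",
    "cdr3_aa": "cdr3",
}


def _parse_bool_column(series: pd.Series, name: str) -> pd.Series:
    out = np.empty(len(series), dtype=bool)
    for pos, v in enumerate(series.astype(str).str.strip().str.lower()):
        if v in ("true", "t"):
            out[pos] = True
        elif v in ("false", "f"):
            out[pos] = False
        else:
            raise ParseError(f"unparseable boolean {series.iloc[pos]!r} in column {name!r}", row=pos + 1)
    return pd.Series(out, index=series.index)


def read_contig_table(path: str | Path) -> pd.DataFrame:
    """Load a 10x-style ``filtered_contig_annotations.csv``.

    Returns a DataFrame with columns :data:`CONTIG_COLUMNS`.  Chains
    outside {TRA, TRB} are mapped to ``other``; gene names normalized;
    boolean dialects True/true accepted, anything else (e.g. "None")
    raises :class:`ParseError` with the row number.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    if "barcode" not in df.columns:
        raise FormatError("contig file lacks a 'barcode' column")
    for col in ("chain", "cdr3_nt", "umis"):
        if col not in df.columns:
            raise FormatError(f"contig file lacks a {col!r} column")
    out = pd.DataFrame(index=df.index)
    out["barcode"] = df["barcode"].str.strip()
    if (out["barcode"] == "").any():
        raise ParseError("empty barcode", row=int((out["barcode"] == "").idxmax()) + 1)
    chain = df["chain"].str.strip().str.upper()
    out["chain"] = chain.where(chain.isin(["TRA", "TRB"]), "other")
    out["v_gene"] = df.get("v_gene", pd.Series("", index=df.index)).map(normalize_gene)
    out["j_gene"] = df.get("j_gene", pd.Series("", index=df.index)).map(normalize_gene)
    out["cdr3_nt"] = df["cdr3_nt"].str.strip().str.upper()
    out["cdr3_aa"] = df.get("cdr3", pd.Series("", index=df.index)).str.strip()
    for col in ("umis", "reads"):
        vals = pd.to_numeric(df.get(col, pd.Series("0", index=df.index)), errors="coerce")
        if vals.isna().any():
            raise ParseError(f"non-numeric {col}", row=int(vals.isna().idxmax()) + 1)
        out[col] = vals.astype(int)
        if (out[col] < 0).any():
            raise ParseError(f"negative {col}", row=int((out[col] < 0).idxmax()) + 1)
    for col in ("productive", "high_confidence"):
        if col in df.columns:
            out[col] = _parse_bool_column(df[col], col)
        else:
            out[col] = True
    return out[CONTIG_COLUMNS]


# ---------------------------------------------------------------------------
# Expression matrices


@dataclass
class ExpressionMatrix:
    """Sparse gene x cell count matrix with per-cell QC covariates."""

    genes: list[str]
    barcodes: list[str]
    counts: sp.csr_matrix = field(repr=False)
    mito_prefix: str = "MT-"
    n_features: np.ndarray = field(init=False, repr=False)
    mito_fraction: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.counts.shape != (len(self.genes), len(self.barcodes)):
            raise FormatError(
                f"matrix is {self.counts.shape}, expected "
                f"({len(self.genes)} genes, {len(self.barcodes)} cells)"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        csc = self.counts.tocsc()
        self.n_features = np.diff(csc.indptr).astype(int)
        totals = np.asarray(self.counts.sum(axis=0)).ravel()
        mito_mask = np.array([g.startswith(self.mito_prefix) for g in self.genes])
        mito = np.asarray(self.counts[mito_mask].sum(axis=0)).ravel() if mito_mask.any() \
            else np.zeros(len(self.barcodes))
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
        self.mito_fraction = frac
        self.cell_totals = totals

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        idx = np.flatnonzero(mask)
        return ExpressionMatrix(
            genes=list(self.genes),
            barcodes=[self.barcodes[i] for i in idx],
            counts=self.counts[:, idx].tocsr(),
            mito_prefix=self.mito_prefix,
        )


def _read_lines(path: str | Path) -> list[str]:
    return [ln.rstrip("\n") for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_expression_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    mito_prefix: str = "MT-",
) -> ExpressionMatrix:
    """Load a MatrixMarket triplet (genes x cells) with its gene and
    barcode lists.  Gene files may be one column (symbol) or 10x-style
    two/three column (id, symbol, type); the symbol column is used."""
    mat = sp.csr_matrix(scipy.io.mmread(matrix_path))
    gene_lines = _read_lines(genes_path)
    genes = [ln.split("\t")[1] if "\t" in ln else ln for ln in gene_lines]
    barcodes = [ln.split("\t")[0] for ln in _read_lines(barcodes_path)]
    if mat.shape[0] != len(genes):
        raise FormatError(f"matrix has {mat.shape[0]} rows but genes file has {len(genes)} entries")
    if mat.shape[1] != len(barcodes):
        raise FormatError(f"matrix has {mat.shape[1]} columns but barcodes file has {len(barcodes)} entries")
    return ExpressionMatrix(genes, barcodes, mat, mito_prefix=mito_prefix)


# ---------------------------------------------------------------------------
# Gene signatures and specificity tables


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: frozenset[str]
    source: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValidationError(f"signature {self.name!r} is empty")


def read_gene_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """One gene symbol per line; duplicates collapsed with a warning."""
    lines = [ln.strip() for ln in _read_lines(path)]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise ValidationError(f"signature file {path} contains no genes")
    if len(set(lines)) < len(lines):
        logger.warning("signature %s contains duplicate genes; collapsing", path)
    return GeneSignature(name=name or Path(path).stem, genes=frozenset(lines))


def read_specificity_table(path: str | Path) -> pd.DataFrame:
    """Public-TCR specificity TSV with at least cdr3_aa and antigen columns."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "cdr3_aa" not in df.columns:
        raise FormatError("specificity table lacks a 'cdr3_aa' column")
    if "antigen" not in df.columns:
        raise FormatError("specificity table lacks an 'antigen' column")
    df = df[df["cdr3_aa"].str.len() > 0]
    if "v_gene" in df.columns:
        df = df.assign(v_gene=df["v_gene"].map(normalize_gene))
    return df.reset_index(drop=True)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Sample manifest TSV: sample_id, compartment, timepoint, platform, path."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "compartment", "timepoint", "platform", "path"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest missing columns {sorted(missing)}")
    return df


def write_clone_table(matrix, path: str | Path) -> None:
    """Serialize a CloneTrackMatrix to TSV (one clone per row, one
    frequency column per sample, then annotation columns).  Frequencies
    are written with ``repr`` precision so a round trip is exact."""
    matrix.to_frame().to_csv(path, sep="\t", index=True, index_label="clone_key")


def read_clone_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"clone_key": str})
    return df.set_index("clone_key")
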