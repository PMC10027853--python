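"""Single-cell QC, normalization, signature scoring, cell-cycle calls,
and one-vs-rest cluster markers.

QC keeps cells below a mitochondrial-fraction ceiling and above a feature
floor (with an optional feature ceiling).  Normalization scales each cell
to a fixed total (default 10,000) and applies log1p.  Signature scores are
either the plain mean of normalized expression over signature genes
(default) or the mean minus expression-bin-matched control genes (the
Seurat AddModuleScore scheme: 24 average-expression bins, 25 controls per
signature gene, seeded).  Cell-cycle phase is called from S and G2/M
scores computed in the bin-control mode.  Cluster markers come from a
one-vs-rest Wilcoxon rank-sum test with Seurat-style log-fold-change and
detection-fraction filters (log fold-change > 0.25, detected in ≥ 20% of
the tested cluster) and BH correction within cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import ExpressionMatrix, GeneSignature

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """log1p(scale_total * count / cell_total), genes x cells, sparse."""

    genes: list[str]
    barcodes: list[str]
    values: sp.csr_matrix = field(repr=False)
    scale_total: float = 1e4

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def qc_filter_cells(
    m: ExpressionMatrix,
    mito_max: float = 0.25,
    features_min: int = 200,
    features_max: int | None = None,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Retain cells with mito_fraction < mito_max and n_features strictly
    between the feature bounds.  Returns the filtered matrix and a report
    of removals per criterion (a cell can count toward several)."""
    if not (0 <= mito_max <= 1):
        raise ValidationError(f"mito_max must be in [0,1], got {mito_max}")
    if features_min < 0 or (features_max is not None and features_max <= features_min):
        raise ValidationError("invalid feature bounds")
    fail_mito = m.mito_fraction >= mito_max
    fail_low = m.n_features <= features_min
    fail_high = (
        m.n_features >= features_max if features_max is not None else np.zeros(len(m.barcodes), bool)
    )
    keep = ~(fail_mito | fail_low | fail_high)
    report = {
        "n_input": len(m.barcodes),
        "removed_mito": int(fail_mito.sum()),
        "removed_low_features": int(fail_low.sum()),
        "removed_high_features": int(fail_high.sum()),
        "n_retained": int(keep.sum()),
    }
    return m.subset_cells(keep), report


def log_normalize(m: ExpressionMatrix, scale_total: float = 1e4) -> NormalizedMatrix:
    """Per-cell depth normalization to ``scale_total`` followed by log1p."""
    totals = np.asarray(m.counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValidationError(
            f"{int((totals == 0).sum())} cells have zero total counts; run QC first"
        )
    mat = m.counts.tocsc().astype(float)
    mat = mat.multiply(scale_total / totals)  # broadcasts over columns
    mat = mat.tocsr()
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(list(m.genes), list(m.barcodes), mat, scale_total)


def _signature_rows(nm: NormalizedMatrix, sig: GeneSignature) -> list[int]:
    idx = nm.gene_index()
    present = [idx[g] for g in sorted(sig.genes) if g in idx]
    missing = sorted(g for g in sig.genes if g not in idx)
    if not present:
        raise ValidationError(
            f"no gene of signature {sig.name!r} is in the matrix; missing: {missing}"
        )
    if missing:
        logger.warning("signature %s: %d genes absent from matrix: %s",
                       sig.name, len(missing), missing[:10])
    return present


def module_score(
    nm: NormalizedMatrix,
    sig: GeneSignature,
    mode: str = "mean",
    n_bins: int = 24,
    ctrl_size: int = 25,
    seed: int = 0,
) -> pd.Series:
    """Per-cell signature score.

    ``mean``: arithmetic mean of normalized expression over the signature
    genes present in the matrix.  ``bin_control``: that mean minus the
    mean over control genes matched on average expression (``ctrl_size``
    controls per signature gene drawn without replacement from the
    signature gene's bin among ``n_bins`` average-expression bins).
    """
    rows = _signature_rows(nm, sig)
    dense_sig = np.asarray(nm.values[rows].mean(axis=0)).ravel()
    if mode == "mean":
        return pd.Series(dense_sig, index=nm.barcodes, name=sig.name)
    if mode != "bin_control":
        raise ValidationError(f"unknown scoring mode {mode!r}")

    avg = np.asarray(nm.values.mean(axis=1)).ravel()
    order = np.argsort(avg, kind="mergesort")
    # Equal-occupancy bins over the expression-ranked gene list.
    bin_of = np.empty(len(avg), dtype=int)
    bin_of[order] = np.minimum((np.arange(len(avg)) * n_bins) // len(avg), n_bins - 1)
    rng = np.random.default_rng(seed)
    control_rows: set[int] = set()
    for r in rows:
        pool = np.flatnonzero(bin_of == bin_of[r])
        take = min(ctrl_size, len(pool))
        control_rows.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl = sorted(control_rows)
    dense_ctrl = np.asarray(nm.values[ctrl].mean(axis=0)).ravel()
    return pd.Series(dense_sig - dense_ctrl, index=nm.barcodes, name=sig.name)


PHASES = ("G1", "S", "G2M")


def assign_cell_cycle(
    nm: NormalizedMatrix,
    s_genes: GeneSignature,
    g2m_genes: GeneSignature,
    seed: int = 0,
) -> pd.DataFrame:
    """Score S and G2/M programs (bin-control mode) and call the phase:
    S if s > g2m and s > 0; G2M if g2m ≥ s and g2m > 0; else G1.
    The tie s == g2m > 0 resolves to G2M."""
    s = module_score(nm, s_genes, mode="bin_control", seed=seed)
    g2m = module_score(nm, g2m_genes, mode="bin_control", seed=seed + 1)
    phase = np.where(
        (g2m >= s) & (g2m > 0), "G2M", np.where((s > g2m) & (s > 0), "S", "G1")
    )
    return pd.DataFrame(
        {"s_score": s, "g2m_score": g2m, "phase": phase}, index=nm.barcodes
    )


def wilcoxon_markers(
    nm: NormalizedMatrix,
    clusters: pd.Series,
    log_fc_min: float = 0.25,
    pct_min: float = 0.20,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum cluster markers.

    log_fc = ln(mean(expm1(x_in)) + 1) − ln(mean(expm1(x_out)) + 1);
    retained markers need log_fc > ``log_fc_min`` and detection in at
    least ``pct_min`` of the tested cluster; q-values are BH within
    cluster.  Clusters smaller than ``min_cells`` are skipped.
    """
    clusters = clusters.reindex(nm.barcodes)
    if clusters.isna().any():
        raise ValidationError("cluster labels missing for some cells")
    labels = sorted(clusters.unique())
    if len(labels) < 2:
        raise ValidationError("need at least two clusters")
    dense = np.asarray(nm.values.todense())
    records = []
    for label in labels:
        in_mask = (clusters == label).to_numpy()
        n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
        if n_in < min_cells or n_out < min_cells:
            logger.warning("cluster %s skipped: %d cells", label, n_in)
            continue
        x_in, x_out = dense[:, in_mask], dense[:, ~in_mask]
        pct_in = (x_in > 0).mean(axis=1)
        pct_out = (x_out > 0).mean(axis=1)
        log_fc = np.log(np.expm1(x_in).mean(axis=1) + 1) - np.log(np.expm1(x_out).mean(axis=1) + 1)
        candidates = np.flatnonzero((log_fc > log_fc_min) & (pct_in >= pct_min))
        if candidates.size == 0:
            continue
        pvals = np.array(
            [
                mannwhitneyu(x_in[g], x_out[g], alternative="two-sided", method="asymptotic")[1]
                for g in candidates
            ]
        )
        qvals = multipletests(pvals, method="fdr_bh")[1]
        for g, p, q in zip(candidates, pvals, qvals):
            records.append(
                {
                    "gene": nm.genes[g],
                    "cluster": label,
                    "log_fc": float(log_fc[g]),
                    "pct_in": float(pct_in[g]),
                    "pct_out": float(pct_out[g]),
                    "p_value": float(p),
                    "q_value": float(q),
                }
            )
    return pd.DataFrame(
        records,
        columns=["gene", "cluster", "log_fc", "pct_in", "pct_out", "p_value", "q_value"],
    )
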