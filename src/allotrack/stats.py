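"""Repertoire diversity, overlap, and clone-dynamics statistics.

Diversity is the inverse Simpson index 1/Σp², the effective number of
equally abundant clones.  Pairwise repertoire similarity is the
Morisita-Horn index, bounded in [0, 1].  Clone dynamics between two
timepoints are classified per clone (emerged / expanded / contracted /
stable / absent) with a two-sided Fisher's exact test on template counts
and Benjamini-Hochberg correction across all clones of the comparison.

All statistics operate on productive template counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import BulkRepertoire


@dataclass
class FrequencyVector:
    """Per-clone productive frequencies (and counts) for one sample.

    ``counts`` is a pandas Series indexed by clone key (any hashable;
    the pipeline uses (cdr3, v_gene, j_gene) tuples or strings).
    """

    sample_id: str
    counts: pd.Series

    def __post_init__(self):
        if len(self.counts) == 0:
            raise ValidationError(f"sample {self.sample_id}: empty frequency vector")
        if (self.counts <= 0).any():
            raise ValidationError(f"sample {self.sample_id}: nonpositive clone counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> pd.Series:
        return self.counts / self.counts.sum()


def clone_key_strings(rep: BulkRepertoire, mode: str = "nt+vj") -> pd.Series:
    """Canonical string key per productive clone row, e.g.
    ``CASS...|TRBV5-1|TRBJ2-7`` for nt+vj / aa+vj modes."""
    prod = rep.productive_clones()
    seq = prod["cdr3_nt"] if mode.startswith("nt") else prod["cdr3_aa"]
    if mode.endswith("+vj"):
        return seq.str.cat([prod["v_gene"], prod["j_gene"]], sep="|")
    return seq.copy()


def clone_frequencies(rep: BulkRepertoire, mode: str = "nt+vj") -> FrequencyVector:
    """Productive-clone frequency vector: p_i = templates_i / Σ templates
    over productive rows only."""
    prod = rep.productive_clones()
    if prod.empty or prod["templates"].sum() == 0:
        raise ValidationError(f"sample {rep.sample_id}: no productive templates")
    keys = clone_key_strings(rep, mode)
    counts = pd.Series(prod["templates"].to_numpy(), index=keys.to_numpy()).groupby(level=0).sum()
    return FrequencyVector(rep.sample_id, counts)


def inverse_simpson(f: FrequencyVector) -> float:
    """Inverse Simpson diversity D = 1 / Σ p_i²; equals the clone count
    for a uniform repertoire and 1 for a monoclonal one."""
    p = f.frequencies.to_numpy(dtype=float)
    return float(1.0 / np.sum(p * p))


def morisita_horn(x: FrequencyVector, y: FrequencyVector) -> float:
    """Morisita-Horn overlap over the union of clone keys:

        MH = 2 Σ x_i y_i / ((d_x + d_y) X Y),   d = Σ c_i² / C²

    Symmetric, 0 for disjoint repertoires, 1 for identical composition.
    """
    union = x.counts.index.union(y.counts.index)
    xi = x.counts.reindex(union, fill_value=0).to_numpy(dtype=float)
    yi = y.counts.reindex(union, fill_value=0).to_numpy(dtype=float)
    X, Y = xi.sum(), yi.sum()
    if X == 0 or Y == 0:
        raise ValidationError("Morisita-Horn undefined for a sample with zero total")
    dx = np.sum(xi * xi) / (X * X)
    dy = np.sum(yi * yi) / (Y * Y)
    return float(2.0 * np.sum(xi * yi) / ((dx + dy) * X * Y))


def fold_expansion(
    k_source: int,
    n_source: int,
    k_reference: int,
    n_reference: int,
    pseudocount: float = 0.5,
) -> float:
    """Frequency ratio source/reference with a pseudocount replacing a
    zero count (denominator totals unchanged)."""
    if k_source < 0 or k_reference < 0:
        raise ValidationError("negative counts")
    if k_source == 0 and k_reference == 0:
        raise ValidationError("clone absent from both samples")
    f_src = (k_source if k_source > 0 else pseudocount) / n_source
    f_ref = (k_reference if k_reference > 0 else pseudocount) / n_reference
    return f_src / f_ref


def fisher_exact_twosided(
    k1: np.ndarray, n1: np.ndarray, k2: np.ndarray, n2: np.ndarray
) -> np.ndarray:
    """Two-sided Fisher's exact test p-values for 2x2 tables
    [[k1, n1-k1], [k2, n2-k2]], vectorized over tables.

    Conditional on the margins the first cell follows a hypergeometric
    distribution; the two-sided p-value sums all outcomes whose
    probability does not exceed the observed one (with the customary
    1 + 1e-7 relative tolerance for floating-point ties).  Tables sharing
    margins are grouped so repertoire-wide screens cost one distribution
    evaluation per distinct margin set.
    """
    k1 = np.atleast_1d(np.asarray(k1, dtype=np.int64))
    k2 = np.atleast_1d(np.asarray(k2, dtype=np.int64))
    n1 = np.broadcast_to(np.asarray(n1, dtype=np.int64), k1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=np.int64), k1.shape)
    if (k1 < 0).any() or (k2 < 0).any() or (k1 > n1).any() or (k2 > n2).any():
        raise ValidationError("cell counts must satisfy 0 <= k <= n")
    p = np.empty(k1.shape, dtype=float)
    m = k1 + k2
    groups: dict[tuple[int, int, int], list[int]] = {}
    for i, key in enumerate(zip(n1.tolist(), n2.tolist(), m.tolist())):
        groups.setdefault(key, []).append(i)
    for (g_n1, g_n2, g_m), idx in groups.items():
        lo = max(0, g_m - g_n2)
        hi = min(g_m, g_n1)
        support = np.arange(lo, hi + 1)
        pmf = hypergeom.pmf(support, g_n1 + g_n2, g_m, g_n1)
        order = np.argsort(pmf, kind="mergesort")
        csum = np.cumsum(pmf[order])
        ranked = pmf[order]
        for i in idx:
            p_obs = pmf[k1[i] - lo]
            # sum of pmf over outcomes with pmf <= p_obs * (1 + 1e-7)
            j = np.searchsorted(ranked, p_obs * (1 + 1e-7), side="right")
            p[i] = min(csum[j - 1], 1.0) if j > 0 else 0.0
    return p


DYNAMICS_STATUSES = ("emerged", "expanded", "contracted", "stable", "absent")


def classify_dynamics(
    pre: pd.Series,
    post: pd.Series,
    n_pre: int | None = None,
    n_post: int | None = None,
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    min_detect: int = 2,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Classify every clone in the union of two samples.

    ``pre`` / ``post`` are count Series indexed by clone key; totals
    default to the Series sums.  Rules, applied per clone:

    - *emerged*: zero pre templates and ≥ ``min_detect`` post templates;
    - *absent*: zero pre templates and fewer than ``min_detect`` post
      templates (likely a sequencing singleton);
    - *expanded* / *contracted*: two-sided Fisher's exact test on
      [(k_pre, N_pre−k_pre), (k_post, N_post−k_post)] significant after
      Benjamini-Hochberg (q < alpha) and fold ≥ threshold (or ≤ 1/threshold);
    - *stable*: everything else.

    Fold changes use the pseudocount rule of :func:`fold_expansion` with
    post as source and pre as reference.
    """
    if (pre < 0).any() or (post < 0).any():
        raise ValidationError("negative counts")
    n_pre = int(pre.sum()) if n_pre is None else int(n_pre)
    n_post = int(post.sum()) if n_post is None else int(n_post)
    if n_pre <= 0 or n_post <= 0:
        raise ValidationError("sample totals must be positive")
    union = pre.index.union(post.index)
    k_pre = pre.reindex(union, fill_value=0).astype(int)
    k_post = post.reindex(union, fill_value=0).astype(int)
    detected = (k_pre + k_post) > 0  # clones seen in neither sample carry no signal
    union, k_pre, k_post = union[detected], k_pre[detected], k_post[detected]

    folds = np.array(
        [
            fold_expansion(b, n_post, a, n_pre, pseudocount)
            for a, b in zip(k_pre.to_numpy(), k_post.to_numpy())
        ]
    )
    pvals = fisher_exact_twosided(k_pre.to_numpy(), n_pre, k_post.to_numpy(), n_post)
    qvals = multipletests(pvals, method="fdr_bh")[1]

    status = np.full(len(union), "stable", dtype=object)
    emerged = (k_pre == 0) & (k_post >= min_detect)
    absent = (k_pre == 0) & (k_post < min_detect)
    significant = (qvals < alpha) & ~emerged.to_numpy() & ~absent.to_numpy()
    status[significant & (folds >= fold_threshold)] = "expanded"
    status[significant & (folds <= 1.0 / fold_threshold)] = "contracted"
    status[emerged.to_numpy()] = "emerged"
    status[absent.to_numpy()] = "absent"

    return pd.DataFrame(
        {
            "k_pre": k_pre.to_numpy(),
            "k_post": k_post.to_numpy(),
            "fold_change": folds,
            "p_value": pvals,
            "q_value": qvals,
            "status": status,
        },
        index=union,
    )


def percent_cluster_matching(
    cluster_clones: list,
    bulk_samples: list[BulkRepertoire],
    mode: str = "aa+vj",
) -> pd.Series:
    """Percentage of a clone set found (≥ 1 productive template) in each
    bulk sample.  ``cluster_clones`` are PairedClonotype objects."""
    from .clonotypes import match_to_bulk

    clones = [c for c in cluster_clones if c.beta is not None]
    if not clones:
        raise ValidationError("empty clone set")
    out = {}
    for bulk in bulk_samples:
        matches = match_to_bulk(clones, bulk, mode)
        out[bulk.sample_id] = 100.0 * matches["matched"].sum() / len(clones)
    return pd.Series(out, name="percent_matching")


def clone_fraction_in_bulk(
    clones: list,
    bulk: BulkRepertoire,
    mode: str = "aa+vj",
) -> pd.Series:
    """Percentage of the bulk repertoire occupied by each clone (0 when
    unmatched); indexed by clone_id."""
    from .clonotypes import match_to_bulk

    matches = match_to_bulk(clones, bulk, mode)
    return pd.Series(
        100.0 * matches["bulk_frequency"].to_numpy(),
        index=matches["clone_id"],
        name=bulk.sample_id,
    )
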