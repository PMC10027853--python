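"""Clonotype definition, multichain resolution, and cross-platform matching.

A cell's clonotype is its paired αβ rearrangement.  Cells carrying more
than one contig per chain (doublets, secondary rearrangements) are resolved
to the highest-expressed contig per chain (UMIs, then reads, then
lexicographic CDR3 nt).  Clones are matched to bulk TCRβ repertoires on
the beta chain under a configurable key:

``nt``      CDR3 nucleotide sequence
``aa``      CDR3 amino-acid sequence
``nt+vj``   CDR3 nt plus V and J gene (allele-stripped, IMGT-normalized)
``aa+vj``   CDR3 aa plus V and J gene — the default for cross-platform
            matching, because nucleotide reporting conventions differ
            between 10x and immunoSEQ while gene calls and CDR3 aa agree.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .io import BulkRepertoire

logger = logging.getLogger(__name__)

MATCH_MODES = ("nt", "aa", "nt+vj", "aa+vj")

DEFAULT_MATCH_MODE = "aa+vj"


@dataclass(frozen=True)
class ClonotypeKey:
    """Identity of a single TCR chain rearrangement."""

    chain: str
    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str

    def match_key(self, mode: str) -> tuple:
        """Equality key under a match mode (chain always included)."""
        if mode not in MATCH_MODES:
            raise ValidationError(f"unknown match mode {mode!r}; expected one of {MATCH_MODES}")
        seq = self.cdr3_nt if mode.startswith("nt") else self.cdr3_aa
        if mode.endswith("+vj"):
            return (self.chain, seq, self.v_gene, self.j_gene)
        return (self.chain, seq)


@dataclass
class PairedClonotype:
    clone_id: str
    alpha: ClonotypeKey | None
    beta: ClonotypeKey | None
    n_cells: int = 0
    cluster_distribution: dict[str, int] = field(default_factory=dict)
    barcodes: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.alpha is None and self.beta is None:
            raise ValidationError("paired clonotype needs at least one chain")


def filter_contigs(contigs: pd.DataFrame) -> pd.DataFrame:
    """Keep productive, high-confidence TRA/TRB contigs with a CDR3."""
    keep = (
        contigs["productive"]
        & contigs["high_confidence"]
        & contigs["chain"].isin(["TRA", "TRB"])
        & (contigs["cdr3_nt"] != "")
    )
    out = contigs[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("no contigs survive filtering (of %d input rows)", len(contigs))
    return out


def resolve_multichain(contigs: pd.DataFrame) -> pd.DataFrame:
    """Per barcode, keep at most one TRA and one TRB: the contig with the
    most UMIs per chain, ties broken by reads then lexicographic cdr3_nt.

    Returns the reduced contig table (≤ 2 rows per barcode).
    """
    if contigs.empty:
        return contigs.copy()
    ranked = contigs.sort_values(
        ["barcode", "chain", "umis", "reads", "cdr3_nt"],
        ascending=[True, True, False, False, True],
        kind="mergesort",
    )
    return ranked.drop_duplicates(["barcode", "chain"], keep="first").reset_index(drop=True)


def _contig_key(row: pd.Series) -> ClonotypeKey:
    return ClonotypeKey(
        chain=row["chain"],
        v_gene=row["v_gene"],
        j_gene=row["j_gene"],
        cdr3_nt=row["cdr3_nt"],
        cdr3_aa=row["cdr3_aa"],
    )


def _hash_clone_id(alpha: ClonotypeKey | None, beta: ClonotypeKey | None) -> str:
    parts = []
    for key in (alpha, beta):
        if key is None:
            parts.append("-")
        else:
            parts.append("|".join((key.chain, key.v_gene, key.j_gene, key.cdr3_nt, key.cdr3_aa)))
    digest = hashlib.sha1("//".join(parts).encode()).hexdigest()
    return f"ct-{digest[:12]}"


def pair_cells(resolved: pd.DataFrame) -> pd.DataFrame:
    """Pivot resolved contigs to one row per barcode with alpha/beta keys.

    Columns: barcode, alpha (ClonotypeKey or None), beta (same).
    """
    rows: dict[str, dict[str, ClonotypeKey | None]] = {}
    for _, row in resolved.iterrows():
        entry = rows.setdefault(row["barcode"], {"alpha": None, "beta": None})
        slot = "alpha" if row["chain"] == "TRA" else "beta"
        entry[slot] = _contig_key(row)
    return pd.DataFrame(
        [{"barcode": bc, "alpha": e["alpha"], "beta": e["beta"]} for bc, e in sorted(rows.items())]
    )


def group_clonotypes(
    cells: pd.DataFrame,
    clusters: pd.Series | dict | None = None,
    mode: str = "nt",
) -> list[PairedClonotype]:
    """Group cells with identical (alpha, beta) keys into clones.

    ``clusters`` maps barcode -> cluster label (optional).  Clones are
    returned ranked by descending ``n_cells`` with a deterministic
    tie-break on the beta CDR3 nt (then alpha CDR3 nt).
    """
    if cells.empty:
        return []
    cluster_of = dict(clusters) if clusters is not None else {}
    groups: dict[tuple, list[tuple[str, ClonotypeKey | None, ClonotypeKey | None]]] = {}
    for _, row in cells.iterrows():
        alpha, beta = row["alpha"], row["beta"]
        if alpha is None and beta is None:
            continue
        gkey = (
            alpha.match_key(mode) if alpha is not None else None,
            beta.match_key(mode) if beta is not None else None,
        )
        groups.setdefault(gkey, []).append((row["barcode"], alpha, beta))
    clones = []
    for members in groups.values():
        barcodes = sorted(bc for bc, _, _ in members)
        alpha, beta = members[0][1], members[0][2]
        dist: dict[str, int] = {}
        for bc in barcodes:
            label = cluster_of.get(bc)
            if label is not None:
                dist[label] = dist.get(label, 0) + 1
        clones.append(
            PairedClonotype(
                clone_id=_hash_clone_id(alpha, beta),
                alpha=alpha,
                beta=beta,
                n_cells=len(barcodes),
                cluster_distribution=dist,
                barcodes=barcodes,
            )
        )
    clones.sort(
        key=lambda c: (
            -c.n_cells,
            c.beta.cdr3_nt if c.beta else "",
            c.alpha.cdr3_nt if c.alpha else "",
        )
    )
    return clones


def bulk_match_index(bulk: BulkRepertoire, mode: str) -> pd.DataFrame:
    """Productive bulk rows keyed for matching under ``mode``.

    Returns a frame indexed by match key (as tuple) with summed templates.
    """
    prod = bulk.productive_clones()
    seq = prod["cdr3_nt"] if mode.startswith("nt") else prod["cdr3_aa"]
    if mode.endswith("+vj"):
        keys = list(zip(["TRB"] * len(prod), seq, prod["v_gene"], prod["j_gene"]))
    else:
        keys = list(zip(["TRB"] * len(prod), seq))
    agg = pd.DataFrame({"key": keys, "templates": prod["templates"].to_numpy()})
    return agg.groupby("key", sort=False)["templates"].sum()


def match_to_bulk(
    clones: list[PairedClonotype],
    bulk: BulkRepertoire,
    mode: str = DEFAULT_MATCH_MODE,
) -> pd.DataFrame:
    """Match single-cell clones against a bulk TCRβ repertoire.

    A clone matches when its beta-chain key equals a bulk row's key under
    ``mode``; the matched frequency sums all matching productive bulk rows
    over the productive template total.  Clones without a beta chain are
    excluded (logged).  Returns a frame with columns clone_id, matched,
    bulk_templates, bulk_frequency.
    """
    if mode not in MATCH_MODES:
        raise ValidationError(f"unknown match mode {mode!r}")
    total = bulk.productive_templates
    if total == 0:
        raise ValidationError(f"bulk sample {bulk.sample_id} has no productive templates")
    index = bulk_match_index(bulk, mode)
    n_no_beta = sum(1 for c in clones if c.beta is None)
    if n_no_beta:
        logger.info("%d clones lack a beta chain and are excluded from matching", n_no_beta)
    records = []
    for clone in clones:
        if clone.beta is None:
            continue
        key = clone.beta.match_key(mode)
        templates = int(index.get(key, 0))
        records.append(
            {
                "clone_id": clone.clone_id,
                "matched": templates > 0,
                "bulk_templates": templates,
                "bulk_frequency": templates / total,
            }
        )
    return pd.DataFrame(records, columns=["clone_id", "matched", "bulk_templates", "bulk_frequency"])


def annotate_specificity(
    clones: list[PairedClonotype],
    spec: pd.DataFrame,
    require_v: bool = False,
) -> pd.DataFrame:
    """Left-join clones to a public-TCR specificity table on beta cdr3_aa.

    Multiple antigen hits are all reported (one row per hit).  With
    ``require_v`` the V gene must also agree.
    """
    records = []
    for clone in clones:
        if clone.beta is None or not clone.beta.cdr3_aa:
            continue
        hits = spec[spec["cdr3_aa"] == clone.beta.cdr3_aa]
        if require_v and "v_gene" in spec.columns:
            hits = hits[hits["v_gene"] == clone.beta.v_gene]
        for _, hit in hits.iterrows():
            records.append(
                {
                    "clone_id": clone.clone_id,
                    "cdr3_aa": clone.beta.cdr3_aa,
                    "antigen": hit["antigen"],
                    "epitope": hit.get("epitope", ""),
                    "source_db": hit.get("source_db", ""),
                }
            )
    return pd.DataFrame(records, columns=["clone_id", "cdr3_aa", "antigen", "epitope", "source_db"])
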