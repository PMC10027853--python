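"""Integration stage: clone x sample tracking matrices, cluster
distributions of matched clones, and phenotype enrichment of emerged
clones.

This is where the MLR-defined clone sets, the bulk repertoires across
compartments/timepoints, and the blood single-cell cluster labels come
together.  A clone is "found" in a bulk dataset when at least one
productive template matches under the configured mode; no frequency floor
is applied to presence calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .clonotypes import PairedClonotype, match_to_bulk
from .errors import ValidationError
from .io import BulkRepertoire

logger = logging.getLogger(__name__)


def clone_label(clone: PairedClonotype, mode: str) -> str:
    """Human-readable beta-chain key used as matrix row label."""
    beta = clone.beta
    if beta is None:
        raise ValidationError(f"clone {clone.clone_id} has no beta chain")
    seq = beta.cdr3_nt if mode.startswith("nt") else beta.cdr3_aa
    if mode.endswith("+vj"):
        return f"{seq}|{beta.v_gene}|{beta.j_gene}"
    return seq


@dataclass
class CloneTrackMatrix:
    """Clone x sample frequency matrix with per-clone annotations.

    ``frequencies``: DataFrame indexed by beta-chain clone key, one column
    per sample (ordered by compartment then timepoint), values in [0, 1]
    (0 = absent).  ``annotations``: per-clone origin cluster label and
    optional specificity.  ``sample_meta``: sample_id -> (compartment,
    timepoint).
    """

    frequencies: pd.DataFrame
    annotations: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def presence(self) -> pd.DataFrame:
        return self.frequencies > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.frequencies, self.annotations], axis=1)

    def compartment_summary(self) -> pd.DataFrame:
        """Per clone-set x sample: number and percentage of set clones
        present."""
        rows = []
        for label, group in self.annotations.groupby("origin_cluster"):
            keys = group.index
            for sample in self.frequencies.columns:
                present = int((self.frequencies.loc[keys, sample] > 0).sum())
                rows.append(
                    {
                        "clone_set": label,
                        "sample_id": sample,
                        "n_clones": len(keys),
                        "n_present": present,
                        "percent_present": 100.0 * present / len(keys),
                    }
                )
        return pd.DataFrame(rows)


def build_tracking_matrix(
    clone_sets: dict[str, list[PairedClonotype]],
    bulk_samples: list[BulkRepertoire],
    mode: str = "aa+vj",
    freq_floor: float = 0.001,
) -> CloneTrackMatrix:
    """Track labeled clone sets across bulk samples.

    The clone universe is the union of the labeled sets; bulk-only clones
    above ``freq_floor`` are appended under the label ``bulk_only`` to
    keep the matrix desk-sized.  Frequencies come from
    :func:`allotrack.clonotypes.match_to_bulk`.
    """
    if not clone_sets or all(len(v) == 0 for v in clone_sets.values()):
        raise ValidationError("at least one non-empty clone set is required")
    if not bulk_samples:
        raise ValidationError("at least one bulk sample is required")

    freq_cols: dict[str, pd.Series] = {}
    labels: dict[str, str] = {}
    ordered_keys: list[str] = []
    for set_label, clones in clone_sets.items():
        betas = [c for c in clones if c.beta is not None]
        for clone in betas:
            key = clone_label(clone, mode)
            if key not in labels:
                labels[key] = set_label
                ordered_keys.append(key)
    for bulk in bulk_samples:
        col = pd.Series(0.0, index=pd.Index(ordered_keys))
        for set_label, clones in clone_sets.items():
            betas = [c for c in clones if c.beta is not None]
            if not betas:
                continue
            matches = match_to_bulk(betas, bulk, mode)
            keys = [clone_label(c, mode) for c in betas]
            for key, freq in zip(keys, matches["bulk_frequency"]):
                col[key] = max(col[key], freq)
        freq_cols[bulk.sample_id] = col

    # Append large bulk-only clones.
    from .stats import clone_frequencies

    extra_keys: list[str] = []
    for bulk in bulk_samples:
        fv = clone_frequencies(bulk, mode)
        big = fv.frequencies[fv.frequencies >= freq_floor]
        for key in big.index:
            if key not in labels:
                labels[key] = "bulk_only"
                extra_keys.append(key)
    if extra_keys:
        for bulk in bulk_samples:
            fv = clone_frequencies(bulk, mode).frequencies
            freq_cols[bulk.sample_id] = pd.concat(
                [freq_cols[bulk.sample_id], fv.reindex(extra_keys, fill_value=0.0)]
            )

    meta = pd.DataFrame(
        {
            "sample_id": [b.sample_id for b in bulk_samples],
            "compartment": [b.compartment for b in bulk_samples],
            "timepoint": [b.timepoint for b in bulk_samples],
        }
    ).set_index("sample_id")
    order = meta.sort_values(["compartment", "timepoint"], kind="mergesort").index
    frequencies = pd.DataFrame(freq_cols)[list(order)]
    annotations = pd.DataFrame(
        {"origin_cluster": [labels[k] for k in frequencies.index]}, index=frequencies.index
    )
    return CloneTrackMatrix(frequencies, annotations, meta)


@dataclass
class ClusterDistribution:
    """Cell counts per transcriptomic cluster for one clone group at one
    timepoint; proportions normalized within the group x timepoint."""

    group: str
    timepoint: str
    counts: dict[str, int]

    @property
    def proportions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {k: v / total for k, v in self.counts.items()}


def map_clones_to_clusters(
    clone_keys: set[str],
    cell_assignments: pd.DataFrame,
    group: str = "matched",
) -> tuple[list[ClusterDistribution], int]:
    """Cluster distributions of cells whose clone key is in the set.

    ``cell_assignments`` columns: barcode, clone_key, cluster, timepoint.
    Returns per-timepoint distributions and the number of clones of the
    set found in at least one cell (e.g. 13 of 19).
    """
    if not clone_keys:
        raise ValidationError("empty clone set")
    hits = cell_assignments[cell_assignments["clone_key"].isin(clone_keys)]
    found = hits["clone_key"].nunique()
    out = []
    for tp in sorted(cell_assignments["timepoint"].unique()):
        sub = hits[hits["timepoint"] == tp]
        if sub.empty:
            logger.warning("group %s: no matched cells at timepoint %s", group, tp)
            continue
        counts = sub.groupby("cluster").size().to_dict()
        out.append(ClusterDistribution(group=group, timepoint=str(tp), counts=counts))
    return out, int(found)


def track_emerged_phenotype(
    dynamics: pd.DataFrame,
    cell_assignments: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[list[ClusterDistribution], pd.DataFrame]:
    """Compare the single-cell phenotype of emerged vs stable clones.

    ``dynamics`` is the output of :func:`allotrack.stats.classify_dynamics`
    indexed by clone key.  For each cluster, overrepresentation of emerged
    clones' cells is tested by Fisher's exact test on the 2x2 table
    (emerged vs stable) x (in-cluster vs out), BH-corrected across
    clusters.  Returns the per-group cluster distributions and the
    enrichment table.
    """
    emerged = set(dynamics.index[dynamics["status"] == "emerged"])
    stable = set(dynamics.index[dynamics["status"] == "stable"])
    cells_e = cell_assignments[cell_assignments["clone_key"].isin(emerged)]
    cells_s = cell_assignments[cell_assignments["clone_key"].isin(stable)]
    if cells_e.empty or cells_s.empty:
        raise ValidationError("emerged or stable group has no cells in the single-cell data")

    dists = []
    for group, cells in (("emerged", cells_e), ("stable", cells_s)):
        counts = cells.groupby("cluster").size().to_dict()
        dists.append(ClusterDistribution(group=group, timepoint="all", counts=counts))

    clusters = sorted(set(cells_e["cluster"]) | set(cells_s["cluster"]))
    n_e, n_s = len(cells_e), len(cells_s)
    records = []
    for cl in clusters:
        a = int((cells_e["cluster"] == cl).sum())
        b = int((cells_s["cluster"] == cl).sum())
        odds, p = fisher_exact([[a, n_e - a], [b, n_s - b]], alternative="two-sided")
        prop_e, prop_s = a / n_e, b / n_s
        records.append(
            {
                "cluster": cl,
                "emerged_cells": a,
                "stable_cells": b,
                "emerged_prop": prop_e,
                "stable_prop": prop_s,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    enrich = pd.DataFrame(records)
    enrich["q_value"] = multipletests(enrich["p_value"], method="fdr_bh")[1]
    enrich["enriched"] = (enrich["q_value"] < alpha) & (
        enrich["emerged_prop"] > enrich["stable_prop"]
    )
    return dists, enrich


def distributions_frame(dists: list[ClusterDistribution]) -> pd.DataFrame:
    rows = []
    for d in dists:
        props = d.proportions
        for cluster, count in sorted(d.counts.items()):
            rows.append(
                {
                    "group": d.group,
                    "timepoint": d.timepoint,
                    "cluster": cluster,
                    "n_cells": count,
                    "proportion": props[cluster],
                }
            )
    return pd.DataFrame(rows, columns=["group", "timepoint", "cluster", "n_cells", "proportion"])
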