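"""End-to-end orchestration: import -> clonotype -> score -> stats -> tracking.

``run_pipeline`` consumes a sample manifest (TSV: sample_id, compartment,
timepoint, platform, path) plus a :class:`PipelineConfig` and writes the
full set of TSV outputs.  Cluster labels for single-cell datasets are an
input (``sc_clusters`` manifest rows) — clustering itself is upstream of
this pipeline.

Outputs (all TSV except the log): ``diversity.tsv``,
``overlap_matrix.tsv``, ``clone_tracking.tsv``, ``dynamics.tsv``,
``cluster_distributions.tsv``, ``enrichment.tsv``, ``markers.tsv``,
``scores.tsv``, ``run_log.txt``.  The run log records versions, seed and
parameters but no timestamps, so a rerun with identical inputs and seed
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clonotypes import (
    PairedClonotype,
    filter_contigs,
    group_clonotypes,
    match_to_bulk,
    pair_cells,
    resolve_multichain,
)
from .errors import AllotrackError, FormatError, ValidationError
from .io import (
    BulkRepertoire,
    read_bulk_repertoire,
    read_contig_table,
    read_expression_mtx,
    read_gene_signature,
    read_manifest,
    read_specificity_table,
)
from .scoring import assign_cell_cycle, log_normalize, module_score, qc_filter_cells, wilcoxon_markers
from .stats import classify_dynamics, clone_frequencies, inverse_simpson, morisita_horn
from .tracking import (
    build_tracking_matrix,
    clone_label,
    distributions_frame,
    map_clones_to_clusters,
    track_emerged_phenotype,
)


@dataclass
class PipelineConfig:
    """Thresholds and modes for one pipeline run."""

    seed: int = 0
    match_mode: str = "aa+vj"
    sc_group_mode: str = "nt"  # within-platform clonotype grouping key
    qc_mito_max: float = 0.25
    qc_features_min: int = 200
    qc_features_max: int | None = None
    scale_total: float = 1e4
    score_mode: str = "mean"
    alpha: float = 0.05
    fold_threshold: float = 2.0
    pseudocount: float = 0.5
    min_detect: int = 2
    freq_floor: float = 0.001
    min_clone_cells: int = 2
    clone_set_clusters: tuple[str, ...] = ("C1", "C2")
    signatures_dir: str | None = None
    specificity_path: str | None = None

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib

        raw = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "clone_set_clusters" in raw:
            raw["clone_set_clusters"] = tuple(raw["clone_set_clusters"])
        return cls(**raw)


@dataclass
class ScDataset:
    sample_id: str
    compartment: str
    timepoint: str
    contigs_path: Path
    expr_dir: Path
    clusters_path: Path


def _resolve(base: Path, p: str) -> Path:
    path = Path(p)
    out = path if path.is_absolute() else base / path
    if not out.exists():
        raise FormatError(f"manifest references missing file: {out}")
    return out


def load_manifest(manifest_path: str | Path) -> tuple[list[BulkRepertoire], dict[str, ScDataset]]:
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    base = manifest_path.parent
    bulks: list[BulkRepertoire] = []
    sc: dict[str, dict] = {}
    for _, row in manifest.iterrows():
        if row["platform"] == "bulk":
            bulks.append(
                read_bulk_repertoire(
                    _resolve(base, row["path"]), row["sample_id"],
                    row["compartment"], row["timepoint"],
                )
            )
        elif row["platform"] in ("sc_vdj", "sc_expr", "sc_clusters"):
            entry = sc.setdefault(
                row["sample_id"],
                {"compartment": row["compartment"], "timepoint": row["timepoint"]},
            )
            entry[row["platform"]] = _resolve(base, row["path"])
        else:
            raise FormatError(f"unknown platform {row['platform']!r} in manifest")
    datasets = {}
    for sid, entry in sc.items():
        for need in ("sc_vdj", "sc_expr", "sc_clusters"):
            if need not in entry:
                raise FormatError(f"single-cell sample {sid} lacks a {need} manifest row")
        datasets[sid] = ScDataset(
            sample_id=sid,
            compartment=entry["compartment"],
            timepoint=entry["timepoint"],
            contigs_path=entry["sc_vdj"],
            expr_dir=entry["sc_expr"].parent,
            clusters_path=entry["sc_clusters"],
        )
    return bulks, datasets


def _sc_clonotypes(ds: ScDataset, mode: str):
    """Contigs -> filtered -> resolved -> paired cells -> clones."""
    contigs = read_contig_table(ds.contigs_path)
    resolved = resolve_multichain(filter_contigs(contigs))
    cells = pair_cells(resolved)
    clusters = pd.read_csv(ds.clusters_path, sep="\t", dtype=str)
    cluster_of = clusters.set_index("barcode")["cluster"]
    clones = group_clonotypes(cells, cluster_of, mode=mode)
    return cells, clusters, clones


def _origin_cluster(clone: PairedClonotype) -> str | None:
    if not clone.cluster_distribution:
        return None
    return max(sorted(clone.cluster_distribution), key=clone.cluster_distribution.get)


def _score_dataset(ds: ScDataset, cfg: PipelineConfig, signatures: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """QC + normalize + signature scores + cell-cycle (+ markers for the
    MLR dataset); returns (scores, markers)."""
    em = read_expression_mtx(
        ds.expr_dir / "matrix.mtx", ds.expr_dir / "genes.tsv", ds.expr_dir / "barcodes.tsv"
    )
    em_qc, report = qc_filter_cells(
        em, cfg.qc_mito_max, cfg.qc_features_min, cfg.qc_features_max
    )
    nm = log_normalize(em_qc, cfg.scale_total)
    scores = pd.DataFrame(index=nm.barcodes)
    for name, sig in signatures.items():
        if name in ("s_phase", "g2m_phase"):
            continue
        scores[name] = module_score(nm, sig, mode=cfg.score_mode, seed=cfg.seed)
    if "s_phase" in signatures and "g2m_phase" in signatures:
        cc = assign_cell_cycle(nm, signatures["s_phase"], signatures["g2m_phase"], seed=cfg.seed)
        scores = scores.join(cc)
    scores.insert(0, "dataset", ds.sample_id)
    scores.index.name = "barcode"
    scores.attrs["qc_report"] = report

    clusters = pd.read_csv(ds.clusters_path, sep="\t", dtype=str).set_index("barcode")["cluster"]
    common = [b for b in nm.barcodes if b in clusters.index]
    markers = pd.DataFrame()
    if len(common) == len(nm.barcodes):
        markers = wilcoxon_markers(nm, clusters.reindex(nm.barcodes))
        markers.insert(0, "dataset", ds.sample_id)
    return scores, markers


def run_pipeline(
    manifest_path: str | Path,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Execute the full analysis and write TSV outputs to ``out_dir``.

    Returns a dict of the in-memory result tables.  Any stage failure is
    re-raised annotated with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "import"
    try:
        bulks, sc_datasets = load_manifest(manifest_path)
        bulk_by_id = {b.sample_id: b for b in bulks}
        base = Path(manifest_path).parent

        signatures = {}
        if config.signatures_dir:
            for p in sorted(Path(config.signatures_dir).glob("*.txt")):
                sig = read_gene_signature(p)
                signatures[sig.name] = sig

        # --- clonotype stage: MLR-defined clone sets
        stage = "clonotype"
        mlr_ds = next(
            (d for d in sc_datasets.values() if d.compartment == "mlr"), None
        )
        clone_sets: dict[str, list[PairedClonotype]] = {}
        if mlr_ds is not None:
            _, _, mlr_clones = _sc_clonotypes(mlr_ds, config.sc_group_mode)
            for clone in mlr_clones:
                origin = _origin_cluster(clone)
                if (
                    origin in config.clone_set_clusters
                    and clone.n_cells >= config.min_clone_cells
                    and clone.beta is not None
                ):
                    clone_sets.setdefault(origin, []).append(clone)

        # --- scoring stage
        stage = "score"
        all_scores, all_markers = [], []
        for ds in sc_datasets.values():
            if signatures:
                scores, markers = _score_dataset(ds, config, signatures)
                all_scores.append(scores)
                if not markers.empty:
                    all_markers.append(markers)
        scores_df = pd.concat(all_scores) if all_scores else pd.DataFrame()
        markers_df = pd.concat(all_markers) if all_markers else pd.DataFrame()

        # --- repertoire statistics stage
        stage = "stats"
        freq = {b.sample_id: clone_frequencies(b, config.match_mode) for b in bulks}
        diversity = pd.DataFrame(
            {
                "sample_id": [b.sample_id for b in bulks],
                "compartment": [b.compartment for b in bulks],
                "timepoint": [b.timepoint for b in bulks],
                "n_clones": [len(freq[b.sample_id].counts) for b in bulks],
                "inverse_simpson": [inverse_simpson(freq[b.sample_id]) for b in bulks],
            }
        )
        ids = [b.sample_id for b in bulks]
        overlap = pd.DataFrame(
            [[morisita_horn(freq[a], freq[b]) for b in ids] for a in ids],
            index=ids, columns=ids,
        )

        blood = sorted(
            (b for b in bulks if b.compartment == "blood"), key=lambda b: b.timepoint
        )
        dynamics_frames = {}
        if len(blood) >= 2:
            ref = blood[0]
            for post in blood[1:]:
                dyn = classify_dynamics(
                    freq[ref.sample_id].counts,
                    freq[post.sample_id].counts,
                    fold_threshold=config.fold_threshold,
                    alpha=config.alpha,
                    min_detect=config.min_detect,
                    pseudocount=config.pseudocount,
                )
                dyn.insert(0, "comparison", f"{ref.sample_id}_vs_{post.sample_id}")
                dynamics_frames[post.sample_id] = dyn
        dynamics_df = (
            pd.concat(dynamics_frames.values()) if dynamics_frames else pd.DataFrame()
        )
        dynamics_df.index.name = "clone_key"

        # --- tracking stage
        stage = "tracking"
        tracking = None
        tracking_frame = pd.DataFrame()
        if clone_sets:
            tracking = build_tracking_matrix(
                clone_sets, bulks, mode=config.match_mode, freq_floor=config.freq_floor
            )
            tracking_frame = tracking.to_frame()
            # Fold expansion of each clone-set clone, MLR vs each blood sample.
            mlr_bulk = bulk_by_id.get("mlr")
            if mlr_bulk is not None:
                mlr_total = mlr_bulk.productive_templates
                for b in blood:
                    col = []
                    for key in tracking_frame.index:
                        k_mlr = int(round(
                            tracking.frequencies.loc[key, "mlr"] * mlr_total
                        )) if "mlr" in tracking.frequencies.columns else 0
                        k_blood = int(round(
                            tracking.frequencies.loc[key, b.sample_id]
                            * freq[b.sample_id].total
                        ))
                        if k_mlr == 0 and k_blood == 0:
                            col.append(np.nan)
                        else:
                            from .stats import fold_expansion

                            col.append(
                                fold_expansion(
                                    k_mlr, mlr_total, k_blood, freq[b.sample_id].total,
                                    config.pseudocount,
                                )
                            )
                    tracking_frame[f"fold_mlr_vs_{b.sample_id}"] = col

            if config.specificity_path:
                spec = read_specificity_table(_resolve(base, config.specificity_path))
                from .clonotypes import annotate_specificity

                annot_rows = []
                for label, clones in clone_sets.items():
                    ann = annotate_specificity(clones, spec)
                    keyed = {
                        clone.clone_id: clone_label(clone, config.match_mode)
                        for clone in clones
                    }
                    if not ann.empty:
                        ann["clone_key"] = ann["clone_id"].map(keyed)
                        annot_rows.append(ann)
                if annot_rows:
                    ann = pd.concat(annot_rows).groupby("clone_key")["antigen"].agg(
                        lambda s: ";".join(sorted(set(s)))
                    )
                    tracking_frame["specificity"] = ann.reindex(tracking_frame.index).fillna("")

        # --- blood single-cell phenotype stage
        stage = "phenotype"
        dist_frames = []
        enrichment = pd.DataFrame()
        blood_ds = next(
            (d for d in sc_datasets.values() if d.compartment == "blood"), None
        )
        if blood_ds is not None:
            cells, clusters, _ = _sc_clonotypes(blood_ds, config.sc_group_mode)
            meta = clusters.set_index("barcode")
            records = []
            for _, row in cells.iterrows():
                if row["beta"] is None or row["barcode"] not in meta.index:
                    continue
                records.append(
                    {
                        "barcode": row["barcode"],
                        "clone_key": clone_label(
                            PairedClonotype("tmp", row["alpha"], row["beta"], 1),
                            config.match_mode,
                        ),
                        "cluster": meta.loc[row["barcode"], "cluster"],
                        "timepoint": meta.loc[row["barcode"], "timepoint"]
                        if "timepoint" in meta.columns
                        else blood_ds.timepoint,
                    }
                )
            assignments = pd.DataFrame(records)
            for label, clones in clone_sets.items():
                keys = {clone_label(c, config.match_mode) for c in clones}
                dists, found = map_clones_to_clusters(keys, assignments, group=f"{label}-matching")
                df = distributions_frame(dists)
                df["clones_found"] = found
                df["clones_total"] = len(keys)
                dist_frames.append(df)
            if dynamics_frames and not assignments.empty:
                last = blood[-1].sample_id
                try:
                    dists, enrichment = track_emerged_phenotype(
                        dynamics_frames[last], assignments, alpha=config.alpha
                    )
                    dist_frames.append(distributions_frame(dists))
                except ValidationError:
                    pass
        distributions = (
            pd.concat(dist_frames, ignore_index=True) if dist_frames else pd.DataFrame()
        )

        # --- write outputs
        stage = "write"
        diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
        overlap.to_csv(out / "overlap_matrix.tsv", sep="\t", index_label="sample_id")
        tracking_frame.to_csv(out / "clone_tracking.tsv", sep="\t", index_label="clone_key")
        dynamics_df.to_csv(out / "dynamics.tsv", sep="\t")
        distributions.to_csv(out / "cluster_distributions.tsv", sep="\t", index=False)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        markers_df.to_csv(out / "markers.tsv", sep="\t", index=False)
        scores_df.to_csv(out / "scores.tsv", sep="\t")
        log_lines = [
            f"allotrack {__version__}",
            f"python {sys.version.split()[0]}",
            f"numpy {np.__version__}",
            f"pandas {pd.__version__}",
            "config:",
        ] + [f"  {f.name} = {getattr(config, f.name)!r}" for f in dataclasses.fields(config)]
        (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    except AllotrackError as exc:
        raise AllotrackError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "diversity": diversity,
        "overlap": overlap,
        "tracking": tracking,
        "tracking_frame": tracking_frame,
        "dynamics": dynamics_df,
        "distributions": distributions,
        "enrichment": enrichment,
        "markers": markers_df,
        "scores": scores_df,
        "clone_sets": clone_sets,
    }
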