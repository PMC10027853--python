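"""Ground-truthed synthetic MLR / repertoire study generator.

Emulates the statistical structure of a single-patient alloreactivity
study: a blood TCRβ repertoire with a heavy-tailed (log-normal) clone
abundance distribution; tissue repertoires sharing a tunable fraction of
blood clones; a designated alloreactive clone subset that is absent from
pre-treatment blood, expands strongly in the MLR and post-treatment
blood, and seeds the rejected kidney but not tumor compartments; a
viral-like subset at high, stable abundance everywhere; and paired
expression/TCR single-cell data with cluster-specific gene programs
(proliferating, cytotoxic, regulatory, interferon, ZNF683-like),
per-cell mitochondrial fractions, and multichain cells with lower-UMI
decoy chains.

Every emitted file is a deterministic function of the config seed; truth
tables recording clone identities, compartment memberships, expansion
folds and per-cell cluster/phase assignments are serialized alongside.
Bulk TSVs use Adaptive immunoSEQ spellings (``TCRBV05-01*01``) while
contigs use IMGT (``TRBV5-1``), exercising the cross-platform gene-name
normalization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import ValidationError
from .io import BulkRepertoire, read_bulk_repertoire

# V/J gene pools: (Adaptive spelling, IMGT spelling).
TRBV_POOL = [
    ("TCRBV02-01*01", "TRBV2"),
    ("TCRBV04-01*01", "TRBV4-1"),
    ("TCRBV05-01*01", "TRBV5-1"),
    ("TCRBV06-05*01", "TRBV6-5"),
    ("TCRBV07-09*01", "TRBV7-9"),
    ("TCRBV09-01*01", "TRBV9"),
    ("TCRBV11-02*01", "TRBV11-2"),
    ("TCRBV12-03*01", "TRBV12-3"),
    ("TCRBV19-01*01", "TRBV19"),
    ("TCRBV27-01*01", "TRBV27"),
    ("TCRBV28-01*01", "TRBV28"),
    ("TCRBV30-01*01", "TRBV30"),
]
TRBJ_POOL = [
    ("TCRBJ01-01*01", "TRBJ1-1"),
    ("TCRBJ01-02*01", "TRBJ1-2"),
    ("TCRBJ01-05*01", "TRBJ1-5"),
    ("TCRBJ02-01*01", "TRBJ2-1"),
    ("TCRBJ02-03*01", "TRBJ2-3"),
    ("TCRBJ02-07*01", "TRBJ2-7"),
]
TRBD_POOL = [("TCRBD01-01*01", "TRBD1"), ("TCRBD02-01*01", "TRBD2")]
TRAV_POOL = ["TRAV1-2", "TRAV8-2", "TRAV12-1", "TRAV13-1", "TRAV22", "TRAV25", "TRAV35", "TRAV41"]
TRAJ_POOL = ["TRAJ12", "TRAJ23", "TRAJ30", "TRAJ33", "TRAJ49"]

# Cell-cycle and program gene sets used by the expression generator.
S_GENES = ["MCM2", "MCM4", "PCNA", "RRM1", "UNG", "GINS2", "CDC45", "DTL"]
G2M_GENES = ["MKI67", "TOP2A", "CCNB1", "BIRC5", "AURKA", "BUB1", "CDK1", "UBE2C"]
# General proliferation machinery, deliberately disjoint from the
# phase-specific S/G2M sets so cluster programs do not bias phase calls.
PROLIF_GENES = ["STMN1", "TUBA1B", "TUBB", "TYMS", "TK1", "HMGB2", "H2AFZ", "DEK"]
CYTOTOXIC_GENES = ["GZMB", "PRF1", "GNLY", "GZMH", "NKG7", "KLRD1"]
REGULATORY_GENES = ["FOXP3", "IKZF2", "IL2RA", "CTLA4"]
INTERFERON_GENES = ["MX1", "ISG15", "OAS1", "IFI6", "IFIT3"]
ZNF683_GENES = ["ZNF683", "CXCR3", "HLA-DRA", "ITGAE"]
ACTIVATION_GENES = ["HLA-DRA", "CD38", "IL2RA", "TNFRSF9", "PDCD1"]
MT_GENES = [f"MT-{g}" for g in
            ("ND1", "ND2", "CO1", "CO2", "ATP8", "ATP6", "CO3", "ND3",
             "ND4L", "ND4", "ND5", "ND6", "CYB")]

# Codons excluding stop codons, for random in-frame CDR3s.
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in _STOPS]


def translate(nt: str) -> str:
    """Translate an in-frame nucleotide sequence to amino acids."""
    if len(nt) % 3:
        raise ValidationError("sequence length not a multiple of 3")
    return str(Seq(nt).translate())


@dataclass(frozen=True)
class CompartmentSpec:
    """One bulk sample of the simulated study."""

    sample_id: str
    compartment: str
    timepoint: str
    depth: int = 100_000
    sharing_fraction: float = 1.0  # fraction of blood background clones present
    include_allo: bool = False
    allo_scale: float = 1.0  # abundance multiplier for alloreactive clones here


@dataclass(frozen=True)
class ClusterSpec:
    label: str
    program: tuple[str, ...]
    effect: float = 4.0  # program genes' means multiplied by (1 + effect)
    cycling: bool = False


# MLR single-cell design: alloreactive cells proliferate (C1), viral-like
# cells are cytotoxic (C2), background cells spread over resting clusters.
MLR_CLUSTERS = (
    ClusterSpec("C0", (), 0.0),
    ClusterSpec("C1", tuple(PROLIF_GENES), 4.0, cycling=True),
    ClusterSpec("C2", tuple(CYTOTOXIC_GENES), 4.0),
    ClusterSpec("C7", tuple(REGULATORY_GENES), 4.0),
    ClusterSpec("C8", tuple(INTERFERON_GENES), 4.0),
)

# Blood non-naive CD8 design: alloreactive clones sit mostly in the
# ZNF683-like cluster, the rest in the proliferating cluster.
BLOOD_CLUSTERS = (
    ClusterSpec("CTL", tuple(CYTOTOXIC_GENES), 4.0),
    ClusterSpec("EM", (), 0.0),
    ClusterSpec("CM", (), 0.0),
    ClusterSpec("ZNF683", tuple(ZNF683_GENES), 4.0),
    ClusterSpec("Proliferating", tuple(PROLIF_GENES), 4.0, cycling=True),
)


def _default_compartments() -> tuple[CompartmentSpec, ...]:
    return (
        CompartmentSpec("blood_pre", "blood", "t0_pre", include_allo=False),
        CompartmentSpec("blood_pembro1", "blood", "t1_pembro1", include_allo=True, allo_scale=3.0),
        CompartmentSpec("blood_pembro2", "blood", "t2_pembro2", include_allo=True, allo_scale=3.0),
        CompartmentSpec("kidney", "kidney", "t1_pembro1", depth=30_000,
                        sharing_fraction=0.5, include_allo=True, allo_scale=10.0),
        CompartmentSpec("lymph_node", "lymph_node", "t0_pre", depth=30_000,
                        sharing_fraction=0.3, include_allo=False),
        CompartmentSpec("skin", "skin", "t2_pembro2", depth=30_000,
                        sharing_fraction=0.3, include_allo=False),
    )


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic bundle.

    Defaults mirror the simulated study conditions: 980 background
    clones plus 20 alloreactive and 15 viral-like, log-normal abundances
    (sigma 2.0), bulk depth 1e5 templates, 50-fold MLR expansion of the
    alloreactive subset, 1500 MLR cells and 4000 blood cells.
    """

    seed: int
    n_background_clones: int = 980
    n_alloreactive: int = 20
    n_viral_like: int = 15
    abundance_sigma: float = 2.0
    abundance_mu: float = 0.0
    allo_fold: float = 50.0
    # Alloreactive clones are modeled as low-frequency but detectable memory
    # clones: their own log-normal (narrower) scaled below the background mean.
    allo_sigma: float = 0.5
    allo_base_scale: float = 1.0
    viral_scale: float = 20.0  # viral-like clones are large, stable clones
    mlr_depth: int = 100_000
    compartments: tuple[CompartmentSpec, ...] = field(default_factory=_default_compartments)
    # single-cell parameters
    n_cells_mlr: int = 1500
    n_cells_blood: int = 4000
    n_background_genes: int = 200
    nb_dispersion: float = 0.5
    mean_cell_depth: float = 1500.0
    mito_beta: tuple[float, float] = (2.0, 12.0)
    low_depth_rate: float = 0.03  # cells emitted with ~no reads (fail feature QC)
    multichain_rate: float = 0.10
    tcr_capture_rate: float = 0.90
    allo_znf683_prop: float = 0.70  # blood: alloreactive cells in ZNF683 cluster
    program_effect: float = 4.0

    def __post_init__(self):
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        for rate in (self.multichain_rate, self.tcr_capture_rate, self.low_depth_rate,
                     self.allo_znf683_prop):
            if not 0 <= rate <= 1:
                raise ValidationError("rates must lie in [0,1]")
        for spec in self.compartments:
            if spec.depth < 1:
                raise ValidationError("depths must be >= 1")
            if not 0 <= spec.sharing_fraction <= 1:
                raise ValidationError("sharing fractions must lie in [0,1]")


def _rng(seed: int, *context: str) -> np.random.Generator:
    """Independent deterministic stream per (seed, context) pair."""
    digest = hashlib.sha256("/".join(context).encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([seed % (2**31), sub])


class MlrStudySimulator:
    """Holds the simulated clone universe and emits all study files."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self.clones = self._make_clone_universe()

    # -- clone universe ---------------------------------------------------

    def _random_clone(self, rng: np.random.Generator, chain: str = "TRB") -> dict:
        n_codons = int(rng.integers(10, 19))  # CDR3 nt length 30-54
        nt = "".join(rng.choice(_CODONS) for _ in range(n_codons))
        aa = translate(nt)
        if chain == "TRB":
            v_adp, v_imgt = TRBV_POOL[int(rng.integers(len(TRBV_POOL)))]
            j_adp, j_imgt = TRBJ_POOL[int(rng.integers(len(TRBJ_POOL)))]
            d_adp, _ = TRBD_POOL[int(rng.integers(len(TRBD_POOL)))]
            return {"cdr3_nt": nt, "cdr3_aa": aa, "v_adaptive": v_adp, "v_imgt": v_imgt,
                    "j_adaptive": j_adp, "j_imgt": j_imgt, "d_adaptive": d_adp}
        return {
            "alpha_cdr3_nt": nt, "alpha_cdr3_aa": aa,
            "alpha_v": TRAV_POOL[int(rng.integers(len(TRAV_POOL)))],
            "alpha_j": TRAJ_POOL[int(rng.integers(len(TRAJ_POOL)))],
        }

    def _make_clone_universe(self) -> pd.DataFrame:
        cfg = self.cfg
        rng = _rng(cfg.seed, "clones")
        n_total = cfg.n_background_clones + cfg.n_alloreactive + cfg.n_viral_like
        rows = []
        seen_nt: set[str] = set()
        for i in range(n_total):
            clone = self._random_clone(rng, "TRB")
            while clone["cdr3_nt"] in seen_nt:
                clone = self._random_clone(rng, "TRB")
            seen_nt.add(clone["cdr3_nt"])
            clone.update(self._random_clone(rng, "TRA"))
            clone["clone_idx"] = i
            rows.append(clone)
        df = pd.DataFrame(rows).set_index("clone_idx")
        kind = np.array(
            ["background"] * cfg.n_background_clones
            + ["alloreactive"] * cfg.n_alloreactive
            + ["viral_like"] * cfg.n_viral_like
        )
        df["kind"] = kind
        base = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, n_total)
        base[df["kind"] == "viral_like"] *= cfg.viral_scale
        is_allo = (df["kind"] == "alloreactive").to_numpy()
        base[is_allo] = cfg.allo_base_scale * rng.lognormal(
            cfg.abundance_mu, cfg.allo_sigma, int(is_allo.sum())
        )
        df["base_abundance"] = base
        return df

    # -- bulk repertoires -------------------------------------------------

    def _compartment_abundance(self, spec: CompartmentSpec) -> pd.Series:
        """Unnormalized clone weights present in one sample (0 = absent)."""
        cfg = self.cfg
        df = self.clones
        w = df["base_abundance"].copy()
        bg = df.index[df["kind"] == "background"]
        if spec.sharing_fraction < 1.0:
            rng = _rng(cfg.seed, "membership", spec.sample_id)
            n_shared = int(round(spec.sharing_fraction * len(bg)))
            shared = rng.choice(bg.to_numpy(), size=n_shared, replace=False)
            dropped = np.setdiff1d(bg.to_numpy(), shared)
            w[dropped] = 0.0
            # Compartment-private clones replace the dropped ones so tissue
            # repertoires are not simply blood subsets.
            priv_rng = _rng(cfg.seed, "private_abundance", spec.sample_id)
            w_priv = pd.Series(
                priv_rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, len(dropped)),
                index=[f"{spec.sample_id}_priv{i}" for i in range(len(dropped))],
            )
            w = pd.concat([w, w_priv])
        allo = df.index[df["kind"] == "alloreactive"]
        if spec.include_allo:
            w[allo] = df.loc[allo, "base_abundance"] * spec.allo_scale
        else:
            w[allo] = 0.0
        return w[w > 0]

    def _private_clone_row(self, sample_id: str, tag: str) -> dict:
        rng = _rng(self.cfg.seed, "private_clone", sample_id, tag)
        return self._random_clone(rng, "TRB")

    def _sample_to_tsv(self, spec: CompartmentSpec, counts: pd.Series, path: Path) -> None:
        """Write template counts as an Adaptive-dialect TSV."""
        records = []
        for key, templates in counts.items():
            if templates == 0:
                continue
            if isinstance(key, str):  # compartment-private clone
                clone = self._private_clone_row(spec.sample_id, key)
            else:
                clone = self.clones.loc[key].to_dict()
            records.append(
                {
                    "rearrangement": clone["cdr3_nt"],
                    "amino_acid": clone["cdr3_aa"],
                    "v_resolved": clone["v_adaptive"],
                    "d_resolved": clone["d_adaptive"],
                    "j_resolved": clone["j_adaptive"],
                    "templates": int(templates),
                    "frame_type": "In",
                }
            )
        pd.DataFrame(records).to_csv(path, sep="\t", index=False)

    def simulate_bulk_repertoire(self, spec: CompartmentSpec, out_dir: Path) -> Path:
        """Draw one bulk sample (multinomial at the configured depth) and
        write it as an immunoSEQ-style TSV.  Returns the file path."""
        if spec.include_allo and spec.depth < self.cfg.n_alloreactive:
            raise ValidationError(
                f"depth {spec.depth} below the {self.cfg.n_alloreactive} clones forced present"
            )
        w = self._compartment_abundance(spec)
        rng = _rng(self.cfg.seed, "bulk", spec.sample_id)
        counts = pd.Series(
            rng.multinomial(spec.depth, (w / w.sum()).to_numpy()), index=w.index
        )
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / f"{spec.sample_id}.tsv"
        self._sample_to_tsv(spec, counts, path)
        return path

    def bulk_counts(self, spec: CompartmentSpec) -> pd.Series:
        """The multinomial template counts for a sample (same stream as
        :meth:`simulate_bulk_repertoire`), for in-memory use."""
        w = self._compartment_abundance(spec)
        rng = _rng(self.cfg.seed, "bulk", spec.sample_id)
        return pd.Series(rng.multinomial(spec.depth, (w / w.sum()).to_numpy()), index=w.index)

    # -- MLR --------------------------------------------------------------

    def simulate_mlr(self, blood_counts: pd.Series) -> pd.Series:
        """MLR repertoire counts: alloreactive clone weights multiplied by
        ``allo_fold`` before multinomial resampling at ``mlr_depth``;
        viral-like and background clones keep their blood weights."""
        cfg = self.cfg
        w = blood_counts[blood_counts > 0].astype(float).copy()
        numeric = [k for k in w.index if not isinstance(k, str)]
        allo = [k for k in numeric if self.clones.loc[k, "kind"] == "alloreactive"]
        w[allo] *= cfg.allo_fold
        rng = _rng(cfg.seed, "mlr")
        return pd.Series(rng.multinomial(cfg.mlr_depth, (w / w.sum()).to_numpy()), index=w.index)

    # -- single-cell ------------------------------------------------------

    def _gene_panel(self, clusters: tuple[ClusterSpec, ...]) -> list[str]:
        program = []
        for spec in clusters:
            program.extend(spec.program)
        program.extend(S_GENES + G2M_GENES + ACTIVATION_GENES)
        seen, ordered = set(), []
        for g in program:
            if g not in seen:
                seen.add(g)
                ordered.append(g)
        background = [f"GENE{i:04d}" for i in range(self.cfg.n_background_genes)]
        return ordered + background + MT_GENES

    def draw_cell_assignments(
        self,
        repertoire_counts: pd.Series,
        kind: str,
        n_cells: int,
        timepoint_split: dict[str, float] | None = None,
    ) -> pd.DataFrame:
        """Assign cells to clones and clusters.

        ``kind`` is ``mlr`` or ``blood``.  Cells are drawn from the clone
        frequency distribution; each cell's cluster follows its clone's
        class: alloreactive -> proliferating cluster (MLR) or a
        ZNF683/proliferating mix (blood); viral-like -> cytotoxic/CTL;
        background -> resting clusters.  Cycling-cluster cells are split
        between S and G2/M phases.
        """
        cfg = self.cfg
        rng = _rng(cfg.seed, "cells", kind)
        keys = list(repertoire_counts.index)
        p = (repertoire_counts / repertoire_counts.sum()).to_numpy()
        draws = rng.choice(len(keys), size=n_cells, p=p)
        timepoints = (
            list(timepoint_split) if timepoint_split else ["t0"]
        )
        tp_p = (
            np.array([timepoint_split[t] for t in timepoints]) if timepoint_split else np.array([1.0])
        )
        tp_p = tp_p / tp_p.sum()
        rows = []
        for i, ci in enumerate(draws):
            key = keys[ci]
            clone_kind = (
                "background" if isinstance(key, str) else self.clones.loc[key, "kind"]
            )
            if kind == "mlr":
                if clone_kind == "alloreactive":
                    cluster = "C1"
                elif clone_kind == "viral_like":
                    cluster = "C2"
                else:
                    cluster = str(rng.choice(["C0", "C0", "C7", "C8"]))
            else:
                if clone_kind == "alloreactive":
                    cluster = "ZNF683" if rng.random() < cfg.allo_znf683_prop else "Proliferating"
                elif clone_kind == "viral_like":
                    cluster = "CTL"
                else:
                    cluster = str(rng.choice(["CTL", "EM", "EM", "CM"]))
            cycling = {c.label for c in (MLR_CLUSTERS if kind == "mlr" else BLOOD_CLUSTERS)
                       if c.cycling}
            phase = str(rng.choice(["S", "G2M"])) if cluster in cycling else "G1"
            rows.append(
                {
                    "barcode": f"{kind}-{i:05d}-1",
                    "clone_key": key,
                    "clone_kind": clone_kind,
                    "cluster": cluster,
                    "phase": phase,
                    "timepoint": str(timepoints[int(rng.choice(len(timepoints), p=tp_p))]),
                }
            )
        return pd.DataFrame(rows)

    def simulate_paired_sc(
        self,
        assignments: pd.DataFrame,
        kind: str,
        out_dir: Path,
    ) -> dict:
        """Emit the MTX triplet, contig CSV, cluster-label TSV and per-cell
        truth for one single-cell dataset.

        Expression: negative-binomial counts per gene with multiplicative
        cluster-program mean shifts; cycling cells additionally express
        their phase program.  Mitochondrial content follows a per-cell
        Beta draw; a ``low_depth_rate`` fraction of cells is emitted at
        near-zero depth so the QC feature floor has true positives.
        TCR: ``tcr_capture_rate`` of cells get their clone's αβ contigs;
        ``multichain_rate`` get an extra decoy chain with strictly lower
        UMI count.
        """
        cfg = self.cfg
        clusters = MLR_CLUSTERS if kind == "mlr" else BLOOD_CLUSTERS
        spec_by_label = {c.label: c for c in clusters}
        genes = self._gene_panel(clusters)
        n_genes, n_cells = len(genes), len(assignments)
        if assignments["clone_key"].nunique() > n_cells:
            raise ValidationError("more clones than cells")
        gene_idx = {g: i for i, g in enumerate(genes)}
        rng = _rng(cfg.seed, "expression", kind)

        base_mean = rng.lognormal(0.0, 1.0, n_genes)
        mt_rows = np.array([gene_idx[g] for g in MT_GENES])
        non_mt = np.setdiff1d(np.arange(n_genes), mt_rows)

        depth_scale = rng.lognormal(0.0, 0.3, n_cells)
        low_depth = rng.random(n_cells) < cfg.low_depth_rate
        depth_scale[low_depth] *= 0.01
        mito_target = rng.beta(*cfg.mito_beta, n_cells)

        data, indices, indptr = [], [], [0]
        truth_rows = []
        for ci in range(n_cells):
            row = assignments.iloc[ci]
            spec = spec_by_label[row["cluster"]]
            mean = base_mean.copy()
            for g in spec.program:
                mean[gene_idx[g]] *= 1.0 + spec.effect
            if row["phase"] == "S":
                for g in S_GENES:
                    mean[gene_idx[g]] *= 1.0 + cfg.program_effect
            elif row["phase"] == "G2M":
                for g in G2M_GENES:
                    mean[gene_idx[g]] *= 1.0 + cfg.program_effect
            # Mito genes scaled to hit the target fraction in expectation.
            f = mito_target[ci]
            mean[mt_rows] = mean[non_mt].sum() * (f / (1 - f)) / len(mt_rows)
            mean *= cfg.mean_cell_depth * depth_scale[ci] / mean.sum()
            # dispersion alpha in var = mu + alpha*mu^2, i.e. NB size 1/alpha
            r = 1.0 / cfg.nb_dispersion
            counts = rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-12)))
            nz = np.flatnonzero(counts)
            data.extend(counts[nz].tolist())
            indices.extend(nz.tolist())
            indptr.append(len(indices))
            total = int(counts.sum())
            mito = int(counts[mt_rows].sum())
            truth_rows.append(
                {
                    "barcode": row["barcode"],
                    "clone_key": row["clone_key"],
                    "clone_kind": row["clone_kind"],
                    "cluster": row["cluster"],
                    "phase": row["phase"],
                    "timepoint": row["timepoint"],
                    "total_counts": total,
                    "n_features": int((counts > 0).sum()),
                    "mito_fraction": mito / total if total else 0.0,
                }
            )

        import scipy.sparse as sp

        mat = sp.csc_matrix(
            (np.array(data), np.array(indices), np.array(indptr)),
            shape=(n_genes, n_cells),
        )
        out_dir.mkdir(parents=True, exist_ok=True)
        self._write_mtx(mat, genes, assignments["barcode"].tolist(), out_dir)
        contigs, truth_chains = self._make_contigs(assignments, kind)
        contigs.to_csv(out_dir / "filtered_contig_annotations.csv", index=False)
        assignments[["barcode", "cluster", "timepoint"]].to_csv(
            out_dir / "cell_clusters.tsv", sep="\t", index=False
        )
        truth = pd.DataFrame(truth_rows).merge(truth_chains, on="barcode", how="left")
        truth.to_csv(out_dir / "truth_cells.tsv", sep="\t", index=False)
        return {"dir": out_dir, "genes": genes, "truth": truth, "contigs": contigs}

    @staticmethod
    def _write_mtx(mat, genes: list[str], barcodes: list[str], out_dir: Path) -> None:
        import scipy.io

        scipy.io.mmwrite(str(out_dir / "matrix.mtx"), mat.tocoo(), field="integer")
        (out_dir / "genes.tsv").write_text("".join(f"{g}\t{g}\n" for g in genes))
        (out_dir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in barcodes))

    def _beta_chain(self, key) -> dict:
        if isinstance(key, str):
            clone = self._private_clone_row(key.split("_priv")[0], key)
            clone.update(self._random_clone(_rng(self.cfg.seed, "private_alpha", key), "TRA"))
        else:
            clone = self.clones.loc[key].to_dict()
        return clone

    def _make_contigs(self, assignments: pd.DataFrame, kind: str):
        cfg = self.cfg
        rng = _rng(cfg.seed, "contigs", kind)
        rows = []
        truth = []
        for _, cell in assignments.iterrows():
            captured = rng.random() < cfg.tcr_capture_rate
            multichain = captured and rng.random() < cfg.multichain_rate
            truth.append(
                {"barcode": cell["barcode"], "tcr_captured": captured, "is_multichain": multichain}
            )
            if not captured:
                continue
            clone = self._beta_chain(cell["clone_key"])
            beta_umis = int(rng.integers(3, 20))
            alpha_umis = int(rng.integers(2, 15))
            contig = 1
            for chain, v, j, nt, aa, umis in (
                ("TRB", clone["v_imgt"], clone["j_imgt"], clone["cdr3_nt"], clone["cdr3_aa"], beta_umis),
                ("TRA", clone["alpha_v"], clone["alpha_j"], clone["alpha_cdr3_nt"],
                 clone["alpha_cdr3_aa"], alpha_umis),
            ):
                rows.append(
                    {
                        "barcode": cell["barcode"],
                        "is_cell": "True",
                        "contig_id": f"{cell['barcode']}_contig_{contig}",
                        "high_confidence": "True",
                        "chain": chain,
                        "v_gene": v,
                        "j_gene": j,
                        "cdr3": aa,
                        "cdr3_nt": nt,
                        "reads": umis * int(rng.integers(20, 40)),
                        "umis": umis,
                        "productive": "True",
                    }
                )
                contig += 1
            if multichain:
                decoy_chain = "TRB" if rng.random() < 0.5 else "TRA"
                true_umis = beta_umis if decoy_chain == "TRB" else alpha_umis
                decoy = self._random_clone(_rng(cfg.seed, "decoy", cell["barcode"]), "TRB")
                if decoy_chain == "TRA":
                    alpha = self._random_clone(_rng(cfg.seed, "decoya", cell["barcode"]), "TRA")
                    v, j, nt, aa = (alpha["alpha_v"], alpha["alpha_j"],
                                    alpha["alpha_cdr3_nt"], alpha["alpha_cdr3_aa"])
                else:
                    v, j, nt, aa = decoy["v_imgt"], decoy["j_imgt"], decoy["cdr3_nt"], decoy["cdr3_aa"]
                rows.append(
                    {
                        "barcode": cell["barcode"],
                        "is_cell": "True",
                        "contig_id": f"{cell['barcode']}_contig_{contig}",
                        "high_confidence": "True",
                        "chain": decoy_chain,
                        "v_gene": v,
                        "j_gene": j,
                        "cdr3": aa,
                        "cdr3_nt": nt,
                        "reads": max(1, true_umis - 1) * 25,
                        "umis": max(1, true_umis - 1),  # strictly below the true chain
                        "productive": "True",
                    }
                )
        return pd.DataFrame(rows), pd.DataFrame(truth)

    # -- bundle -----------------------------------------------------------

    def clone_truth_frame(self) -> pd.DataFrame:
        df = self.clones.copy()
        df["true_fold"] = np.where(df["kind"] == "alloreactive", self.cfg.allo_fold, 1.0)
        for spec in self.cfg.compartments:
            w = self._compartment_abundance(spec)
            df[f"in_{spec.sample_id}"] = [k in w.index for k in df.index]
        return df

    def write_signatures(self, out_dir: Path) -> dict[str, Path]:
        out_dir.mkdir(parents=True, exist_ok=True)
        sigs = {
            "proliferation": PROLIF_GENES,
            "s_phase": S_GENES,
            "g2m_phase": G2M_GENES,
            "activation": ACTIVATION_GENES,
            "viral_reactive": CYTOTOXIC_GENES,
        }
        paths = {}
        for name, genes in sigs.items():
            p = out_dir / f"{name}.txt"
            p.write_text("".join(f"{g}\n" for g in genes))
            paths[name] = p
        return paths

    def write_specificity_table(self, path: Path) -> None:
        """Public-TCR table annotating viral-like clones with an influenza
        antigen, mimicking a VDJdb/McPAS lookup file."""
        viral = self.clones[self.clones["kind"] == "viral_like"].head(5)
        df = pd.DataFrame(
            {
                "cdr3_aa": viral["cdr3_aa"],
                "v_gene": viral["v_imgt"],
                "antigen": "influenza M1",
                "epitope": "GILGFVFTL",
                "source_db": "synthetic-public-tcr",
            }
        )
        df.to_csv(path, sep="\t", index=False)

    def simulate_bundle(self, out_dir: str | Path) -> Path:
        """Write the full study bundle: bulk TSVs for every compartment,
        the MLR repertoire, MLR and blood single-cell datasets, signature
        files, the specificity table, a manifest, and truth tables.
        Returns the manifest path."""
        cfg = self.cfg
        out = Path(out_dir)
        bulk_dir = out / "bulk"
        manifest_rows = []
        counts_by_sample = {}
        for spec in cfg.compartments:
            path = self.simulate_bulk_repertoire(spec, bulk_dir)
            counts_by_sample[spec.sample_id] = self.bulk_counts(spec)
            manifest_rows.append(
                {
                    "sample_id": spec.sample_id,
                    "compartment": spec.compartment,
                    "timepoint": spec.timepoint,
                    "platform": "bulk",
                    "path": str(path.relative_to(out)),
                }
            )
        # MLR repertoire derived from the post-treatment blood sample.
        mlr_source = "blood_pembro2"
        mlr_counts = self.simulate_mlr(counts_by_sample[mlr_source])
        mlr_spec = CompartmentSpec("mlr", "mlr", "t2_pembro2", depth=cfg.mlr_depth)
        self._sample_to_tsv(mlr_spec, mlr_counts, bulk_dir / "mlr.tsv")
        manifest_rows.append(
            {"sample_id": "mlr", "compartment": "mlr", "timepoint": "t2_pembro2",
             "platform": "bulk", "path": "bulk/mlr.tsv"}
        )

        mlr_cells = self.draw_cell_assignments(mlr_counts, "mlr", cfg.n_cells_mlr)
        self.simulate_paired_sc(mlr_cells, "mlr", out / "sc_mlr")
        blood_cells = self.draw_cell_assignments(
            counts_by_sample["blood_pembro1"].add(
                counts_by_sample["blood_pembro2"], fill_value=0
            ),
            "blood",
            cfg.n_cells_blood,
            timepoint_split={"t1_pembro1": 0.5, "t2_pembro2": 0.5},
        )
        self.simulate_paired_sc(blood_cells, "blood", out / "sc_blood")
        for sc_id, comp, tp, d in (
            ("sc_mlr", "mlr", "t2_pembro2", "sc_mlr"),
            ("sc_blood", "blood", "t1_pembro1", "sc_blood"),
        ):
            for platform, fname in (
                ("sc_vdj", "filtered_contig_annotations.csv"),
                ("sc_expr", "matrix.mtx"),
                ("sc_clusters", "cell_clusters.tsv"),
            ):
                manifest_rows.append(
                    {"sample_id": sc_id, "compartment": comp, "timepoint": tp,
                     "platform": platform, "path": f"{d}/{fname}"}
                )
        self.write_signatures(out / "signatures")
        self.write_specificity_table(out / "public_tcrs.tsv")
        self.clone_truth_frame().to_csv(out / "truth_clones.tsv", sep="\t")
        manifest_path = out / "manifest.tsv"
        pd.DataFrame(manifest_rows).to_csv(manifest_path, sep="\t", index=False)
        return manifest_path


# -- module-level conveniences matching the operation names -----------------


def simulate_bulk_repertoire(cfg: SimConfig, compartment: str, timepoint: str,
                             out_dir: str | Path) -> BulkRepertoire:
    """Simulate and immediately re-read one bulk sample for the named
    compartment/timepoint of the configured study."""
    sim = MlrStudySimulator(cfg)
    for spec in cfg.compartments:
        if spec.compartment == compartment and spec.timepoint == timepoint:
            path = sim.simulate_bulk_repertoire(spec, Path(out_dir))
            return read_bulk_repertoire(path, spec.sample_id, compartment, timepoint)
    raise ValidationError(f"no configured sample for {compartment}/{timepoint}")


def simulate_study(cfg: SimConfig, out_dir: str | Path) -> Path:
    """Emit the full synthetic study bundle; returns the manifest path."""
    return MlrStudySimulator(cfg).simulate_bundle(out_dir)
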