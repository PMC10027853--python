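import numpy as np
import pandas as pd
import pytest

from allotrack.simulate import CompartmentSpec, MlrStudySimulator, SimConfig


def small_sim_config(seed: int = 7) -> SimConfig:
    """Scaled-down study used by unit tests (the acceptance suite uses
    the full default configuration)."""
    return SimConfig(
        seed=seed,
        n_background_clones=150,
        n_alloreactive=10,
        n_viral_like=8,
        mlr_depth=20_000,
        n_cells_mlr=400,
        n_cells_blood=800,
        n_background_genes=120,
        compartments=(
            CompartmentSpec("blood_pre", "blood", "t0_pre", depth=20_000),
            CompartmentSpec("blood_pembro1", "blood", "t1_pembro1", depth=20_000,
                            include_allo=True, allo_scale=3.0),
            CompartmentSpec("blood_pembro2", "blood", "t2_pembro2", depth=20_000,
                            include_allo=True, allo_scale=3.0),
            CompartmentSpec("kidney", "kidney", "t1_pembro1", depth=10_000,
                            sharing_fraction=0.5, include_allo=True, allo_scale=10.0),
            CompartmentSpec("lymph_node", "lymph_node", "t0_pre", depth=10_000,
                            sharing_fraction=0.3),
            CompartmentSpec("skin", "skin", "t2_pembro2", depth=10_000,
                            sharing_fraction=0.3),
        ),
    )


@pytest.fixture(scope="session")
def small_sim() -> MlrStudySimulator:
    return MlrStudySimulator(small_sim_config())


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_sim):
    """The small study bundle written to disk once per session."""
    out = tmp_path_factory.mktemp("bundle")
    manifest = small_sim.simulate_bundle(out)
    return {"dir": out, "manifest": manifest, "sim": small_sim}


@pytest.fixture()
def bulk_tsv(tmp_path):
    """Writer for minimal immunoSEQ-style TSVs."""

    def write(rows, name="sample.tsv", columns=None):
        cols = columns or [
            "rearrangement", "amino_acid", "v_resolved", "d_resolved",
            "j_resolved", "templates", "frame_type",
        ]
        path = tmp_path / name
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
        return path

    return write


@pytest.fixture()
def contig_csv(tmp_path):
    def write(rows, name="filtered_contig_annotations.csv"):
        cols = [
            "barcode", "is_cell", "contig_id", "high_confidence", "chain",
            "v_gene", "j_gene", "cdr3", "cdr3_nt", "reads", "umis", "productive",
        ]
        path = tmp_path / name
        pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
        return path

    return write


def random_counts(rng: np.random.Generator, n_clones: int, depth: int) -> pd.Series:
    w = rng.lognormal(0, 1.5, n_clones)
    counts = rng.multinomial(depth, w / w.sum())
    return pd.Series(counts, index=[f"clone{i}" for i in range(n_clones)])
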