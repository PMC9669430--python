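import numpy as np
import pandas as pd
import pytest

import lncflow as lf

#: fixed seed for the bundled default dataset used across tests
DATASET_SEED = 11


@pytest.fixture(scope="session")
def sim_config() -> lf.SimulationConfig:
    return lf.SimulationConfig(seed=DATASET_SEED)


@pytest.fixture(scope="session")
def dataset(sim_config):
    """In-memory default synthetic dataset: annotation, genome, truth,
    candidates and their sequences."""
    annotation, genome, truth = lf.simulate_genome(sim_config)
    candidates, seqs = lf.simulate_assembly(annotation, genome, truth, sim_config)
    return {
        "config": sim_config,
        "annotation": annotation,
        "genome": genome,
        "truth": truth,
        "candidates": candidates,
        "seqs": seqs,
    }


@pytest.fixture(scope="session")
def pipeline_out(tmp_path_factory):
    """A full end-to-end pipeline run on the default dataset."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = lf.PipelineConfig(outdir=str(outdir), seed=DATASET_SEED)
    manifest = lf.run_pipeline(cfg)
    return {"config": cfg, "outdir": outdir, "manifest": manifest}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def toy_counts(
    counts: np.ndarray,
    lengths=None,
    groups=("group1", "group1", "group2", "group2"),
) -> lf.CountMatrix:
    """Small CountMatrix builder for unit tests."""
    counts = np.atleast_2d(np.asarray(counts))
    n_feat, n_samp = counts.shape
    fids = [f"f{i}" for i in range(n_feat)]
    sids = [f"s{j}" for j in range(n_samp)]
    if lengths is None:
        lengths = [1000] * n_feat
    return lf.CountMatrix(
        counts=pd.DataFrame(counts, index=fids, columns=sids),
        groups=dict(zip(sids, groups)),
        lengths=pd.Series(lengths, index=fids),
    )
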