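import numpy as np
import pytest
from hypothesis import settings

from mendelmap import (
    CohortGenotypes,
    Pedigree,
    PedigreeSample,
    read_annotation,
)
from mendelmap.simulate import SimConfig, build_cohort, make_gene_fixture

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


STUDY_SAMPLES = ["foal1", "foal2", "dam1", "dam2", "ctrl1", "ctrl2", "ctrl3", "ctrl4"]


def study_pedigree() -> Pedigree:
    """Two affected foals with listed dams plus four unrelated controls."""
    rows = [
        PedigreeSample("foal1", "FAM1", None, "dam1", 1, "affected"),
        PedigreeSample("foal2", "FAM1", None, "dam2", 2, "affected"),
        PedigreeSample("dam1", "FAM1", None, None, 2, "unaffected"),
        PedigreeSample("dam2", "FAM1", None, None, 2, "unaffected"),
        PedigreeSample("ctrl1", "FAM1", None, None, 1, "unaffected"),
        PedigreeSample("ctrl2", "FAM1", None, None, 2, "unaffected"),
        PedigreeSample("ctrl3", "FAM1", None, None, 1, "unaffected"),
        PedigreeSample("ctrl4", "FAM1", None, None, 2, "unaffected"),
    ]
    return Pedigree(rows)


def make_cohort(gt_rows, pos=None, chrom="chr1", qual=50.0, samples=None):
    """Small hand-rolled cohort from a list of per-site dosage rows."""
    gt = np.asarray(gt_rows, dtype=np.int8)
    n, k = gt.shape
    samples = samples if samples is not None else [f"s{i}" for i in range(k)]
    pos = pos if pos is not None else list(range(1000, 1000 + 1000 * n, 1000))
    quals = np.full(n, qual, dtype=float) if np.isscalar(qual) else np.asarray(qual)
    return CohortGenotypes(
        samples, [chrom] * n, pos, ["A"] * n, ["T"] * n, quals, gt
    )


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def sim_core(sim_config):
    return build_cohort(sim_config)


@pytest.fixture(scope="session")
def gene_models(sim_config, tmp_path_factory):
    gff, fasta = make_gene_fixture(sim_config, tmp_path_factory.mktemp("genefix"))
    return read_annotation(gff, fasta)


@pytest.fixture(scope="session")
def gene_model(gene_models):
    return gene_models[0]
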