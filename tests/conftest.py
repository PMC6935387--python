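"""Shared fixtures: one session-scoped synthetic dataset and pipeline run."""

import logging

import pytest

from splicechar.annotation import load_annotation, load_genome
from splicechar.pipeline import RunConfig, run
from splicechar.synthetic import SyntheticConfig, generate_dataset

logging.getLogger("splicechar").setLevel(logging.ERROR)

FIXTURE_SEED = 11


def small_config(**overrides) -> SyntheticConfig:
    """Fixture-scale study conditions (full pipeline in ~1 s)."""
    kwargs = dict(
        seed=FIXTURE_SEED,
        n_genes=150,
        n_ri_events=20,
        n_se_events=16,
        n_multikind_genes=4,
        n_alt_events=2,
        n_decoy_events=3,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("dataset")
    cfg = small_config()
    paths = generate_dataset(cfg, outdir)
    return {"dir": outdir, "config": cfg, **paths}


@pytest.fixture(scope="session")
def run_config_kwargs(dataset):
    return dict(
        genome=str(dataset["fasta"]),
        gtf=str(dataset["gtf"]),
        rmats_dir=str(dataset["rmats_dir"]),
        expression=str(dataset["expression"]),
        g1_is_wildtype=True,
        seed=7,
        external_pool_size=60,
        n_perm=200,
    )


@pytest.fixture(scope="session")
def pipeline_run(dataset, run_config_kwargs, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    config = RunConfig(outdir=str(outdir), **run_config_kwargs)
    report = run(config)
    return {"outdir": outdir, "report": report, "config": config}


@pytest.fixture(scope="session")
def genome(dataset):
    return load_genome(dataset["fasta"])


@pytest.fixture(scope="session")
def genes(dataset):
    return load_annotation(dataset["gtf"])
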