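import os
import sys

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, os.path.dirname(__file__))  # make _oracles importable

from mirquant import GeneratorParams, RunConfig, run_pipeline
from mirquant.synthdata import generate

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_run_config(ds, **overrides) -> RunConfig:
    """RunConfig pointed at a generated synthetic dataset."""
    kwargs = dict(
        mature=os.path.join(ds.outdir, "mature.fa"),
        hairpin=os.path.join(ds.outdir, "hairpin.fa"),
        samples=[ds.fastq_paths[s] for s in ds.sample_names],
        sample_names=list(ds.sample_names),
        adapter=ds.params.adapter,
        genome=os.path.join(ds.outdir, "genome.fa"),
        out=os.path.join(ds.outdir, "run"),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """4 samples x 3000 reads with mild errors and background noise."""
    params = GeneratorParams(
        n_samples=4, reads_per_sample=3000, error_rate=0.005, noise_fraction=0.05
    )
    outdir = tmp_path_factory.mktemp("synth_small")
    return generate(params, outdir=str(outdir), seed=101)


@pytest.fixture(scope="session")
def small_run(small_dataset):
    """Filtered pipeline run on the small dataset (default settings)."""
    return run_pipeline(make_run_config(small_dataset))


@pytest.fixture(scope="session")
def small_run_nofilter(small_dataset):
    """Same run with the cross-sample noise filter disabled."""
    cfg = make_run_config(
        small_dataset,
        apply_filter=False,
        out=os.path.join(small_dataset.outdir, "run_nofilter"),
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def clean_dataset(tmp_path_factory):
    """4 samples x 4000 error-free, noise-free reads (exact-recovery regime)."""
    params = GeneratorParams(
        n_samples=4,
        reads_per_sample=4000,
        error_rate=0.0,
        noise_fraction=0.0,
        decoy_reads_per_sample=0,
    )
    outdir = tmp_path_factory.mktemp("synth_clean")
    return generate(params, outdir=str(outdir), seed=202)


@pytest.fixture(scope="session")
def clean_run(clean_dataset):
    cfg = make_run_config(clean_dataset, apply_filter=False)
    return run_pipeline(cfg)
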