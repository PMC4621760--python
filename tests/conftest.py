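import pathlib

import pytest

from auxiaa import pipeline as pl
from auxiaa import synthetic_data as sd

SEED = 1


@pytest.fixture(scope="session")
def soy_dataset() -> sd.SyntheticDataset:
    return sd.simulate_dataset(sd.SimConfig(seed=SEED, species="soybean"))


@pytest.fixture(scope="session")
def chick_dataset() -> sd.SyntheticDataset:
    return sd.simulate_dataset(sd.SimConfig(seed=SEED, species="chickpea"))


def _write(ds, root) -> pathlib.Path:
    out = root / ds.config.species
    sd.write_dataset(ds, out)
    return out


def _config(dirpath, outdir, **overrides) -> pl.PipelineConfig:
    kwargs = dict(
        proteome=str(dirpath / "proteome.fa"),
        gff3=str(dirpath / "genes.gff3"),
        genome=str(dirpath / "genome.fa"),
        cds=str(dirpath / "cds.fa"),
        te_bed=str(dirpath / "te.bed"),
        anchors=str(dirpath / "anchors.tsv"),
        counts=str(dirpath / "counts.tsv"),
        library_sizes=str(dirpath / "library_sizes.tsv"),
        stress_counts=str(dirpath / "stress_counts.tsv"),
        outdir=str(outdir),
    )
    kwargs.update(overrides)
    return pl.PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def soy_dir(soy_dataset, tmp_path_factory) -> pathlib.Path:
    return _write(soy_dataset, tmp_path_factory.mktemp("data"))


@pytest.fixture(scope="session")
def chick_dir(chick_dataset, tmp_path_factory) -> pathlib.Path:
    return _write(chick_dataset, tmp_path_factory.mktemp("data"))


@pytest.fixture(scope="session")
def make_config():
    return _config


@pytest.fixture(scope="session")
def soy_summary(soy_dir, tmp_path_factory):
    cfg = _config(soy_dir, tmp_path_factory.mktemp("run_soy"))
    return pl.run_pipeline(cfg), cfg


@pytest.fixture(scope="session")
def chick_summary(chick_dir, tmp_path_factory):
    cfg = _config(chick_dir, tmp_path_factory.mktemp("run_chick"))
    return pl.run_pipeline(cfg), cfg
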