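import pathlib

import pysam
import pytest

from omixlink import FixtureConfig, generate_cohort_fixture, nmd_worked_example_fixture
from omixlink.pipeline import RunConfig, load_manifest, run_classify


@pytest.fixture(scope="session")
def nmd_example_dir(tmp_path_factory) -> pathlib.Path:
    d = tmp_path_factory.mktemp("nmd_example")
    nmd_worked_example_fixture(d)
    return d


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory) -> pathlib.Path:
    """A small two-sample noiseless cohort with every role represented."""
    d = tmp_path_factory.mktemp("cohort")
    generate_cohort_fixture(FixtureConfig.uniform(n_samples=2, seed=42, n_sites=60), d)
    return d


@pytest.fixture(scope="session")
def cohort_tables(cohort_dir):
    samples, ann, ref = load_manifest(cohort_dir / "manifest.json")
    out = cohort_dir / "out"
    return run_classify(
        RunConfig(samples=samples, annotation=ann, reference_tpm=ref, out_dir=out)
    )


def run_pipeline(fixture_dir, out_name="out", **run_kwargs):
    samples, ann, ref = load_manifest(fixture_dir / "manifest.json")
    return run_classify(
        RunConfig(
            samples=samples,
            annotation=ann,
            reference_tpm=ref,
            out_dir=fixture_dir / out_name,
            **run_kwargs,
        )
    )


@pytest.fixture()
def make_fasta(tmp_path):
    """Write a one-contig FASTA and return an open pysam.FastaFile."""
    handles = []

    def _make(seq: str, name: str = "chr1"):
        path = tmp_path / f"{name}_{len(handles)}.fa"
        path.write_text(f">{name}\n{seq}\n")
        pysam.faidx(str(path))
        fh = pysam.FastaFile(str(path))
        handles.append(fh)
        return fh

    yield _make
    for fh in handles:
        fh.close()
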