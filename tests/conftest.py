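import numpy as np
import pytest

import dbgfeat as d

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture(scope="session")
def small_community(tmp_path_factory):
    """A tiny labelled community: 2 groups x 3 samples, one 500 bp marker each."""
    out = tmp_path_factory.mktemp("small_community")
    spec = d.CommunitySpec(
        n_background_genomes=3,
        genome_length=3000,
        n_groups=2,
        samples_per_group=3,
        markers_per_group=1,
        marker_length=500,
        coverage=20.0,
        seed=11,
    )
    manifest = d.generate_community(spec, out)
    return manifest


@pytest.fixture(scope="session")
def small_tables(small_community):
    return {
        sid: d.count_sample_file(p, k=31, min_count=2)
        for sid, p in small_community.sample_fastas.items()
    }


@pytest.fixture(scope="session")
def small_labels(small_community):
    return d.GroupLabels(dict(small_community.assignment))


@pytest.fixture(scope="session")
def default_community(tmp_path_factory):
    """The default study conditions: 2 groups x 6 samples, 2 kb markers, 30x, no errors."""
    out = tmp_path_factory.mktemp("default_community")
    return d.generate_community(d.CommunitySpec(), out)


@pytest.fixture(scope="session")
def default_run(default_community, tmp_path_factory):
    """Full unique-mode supervised run on the default community."""
    out = tmp_path_factory.mktemp("default_run")
    cfg = d.PipelineConfig(
        mode="unique",
        out_dir=out,
        reads_dir=default_community.reads_dir,
        metadata=default_community.metadata_path,
        seed=42,
    )
    summary = d.run_supervised(cfg)
    return out, summary
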