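import pytest

from taxomap.pipeline import DatabaseInput, RunConfig, run_pipeline
from taxomap.sam_filtering import FilterConfig
from taxomap.synthetic import default_community, generate, paired_community
from taxomap.taxonomy import load_taxonomy_tsv


@pytest.fixture(scope="session")
def single_end_bundle(tmp_path_factory):
    """The single-end planted-recovery community (8 species + 4 contaminants)."""
    return generate(default_community(7), tmp_path_factory.mktemp("fixture_se"))


@pytest.fixture(scope="session")
def paired_bundle(tmp_path_factory):
    """The paired-end community with a decoy database and a fullmode gene db."""
    return generate(paired_community(11), tmp_path_factory.mktemp("fixture_pe"))


def run_bundle(bundle, **criteria_kwargs):
    """Run the full pipeline on a generated fixture bundle."""
    from taxomap.postprocess import CriteriaConfig

    spec = bundle.spec
    cfg = RunConfig(
        databases=[DatabaseInput(db, bundle.sam_paths[db.name]) for db in spec.databases],
        taxonomy=load_taxonomy_tsv(bundle.taxonomy_path),
        context=bundle.context,
        filter_config=FilterConfig(paired=spec.paired),
        criteria=CriteriaConfig(**criteria_kwargs),
        levels=("strain", "species", "genus", "family", "superkingdom"),
    )
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def single_end_result(single_end_bundle):
    return run_bundle(single_end_bundle)


@pytest.fixture(scope="session")
def paired_result(paired_bundle):
    return run_bundle(paired_bundle)
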