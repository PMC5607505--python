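import pytest

from fedsim import fixtures, pipeline
from fedsim import registry as reg
from fedsim.fixtures import CANONICAL_INCHIKEY, FIXTURE_URIS


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """The offline fixture bundle (graphs + registry + manifest)."""
    return fixtures.build_fixture_bundle(tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def registry(bundle):
    return reg.load_registry(bundle.registry_path)


@pytest.fixture(scope="session")
def bindings(bundle):
    return fixtures.local_bindings(bundle.directory)


@pytest.fixture(scope="session")
def worked_example(registry, bindings):
    """Targets run for the reference drug with the Test dataset added."""
    return pipeline.run_template(
        registry,
        "Biology",
        "Targets",
        1,
        CANONICAL_INCHIKEY,
        bindings,
        added=fixtures.test_dataset_spec(),
    )


@pytest.fixture(scope="session")
def profiles(worked_example, bindings):
    """The eight entity profiles of the worked example, predicate-selected."""
    result, _ = pipeline.collect_profiles(worked_example, bindings)
    return result


@pytest.fixture(scope="session")
def uri_of():
    """Shorthand lookup: 'URI_1' .. 'URI_8' -> full URI."""
    return FIXTURE_URIS.__getitem__
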