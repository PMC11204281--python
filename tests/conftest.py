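import pytest

from dnacodec import ConstraintParams, PrimerLibrary
from dnacodec.fixtures import REFERENCE_PRIMER, REFERENCE_PRIMER_ID, generate_primer_library


@pytest.fixture(scope="session")
def params() -> ConstraintParams:
    return ConstraintParams()


@pytest.fixture(scope="session")
def reference_library() -> PrimerLibrary:
    """The single built-in upstream primer."""
    return PrimerLibrary([(REFERENCE_PRIMER_ID, REFERENCE_PRIMER)])


@pytest.fixture(scope="session")
def small_library() -> PrimerLibrary:
    """Ten seeded random primers for pipeline tests."""
    return generate_primer_library(10, seed=11)
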