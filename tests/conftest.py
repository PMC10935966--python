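import pytest

from imageforge.core import LayerConfig, PackageRequest
from imageforge.fixtures import (
    MockSandboxBackend,
    PackageEntry,
    RegistrySpec,
    build_mock_registry,
)


@pytest.fixture
def diamond_registry():
    """a -> {b, c}; b -> d; c -> d; d has two versions."""
    spec = RegistrySpec(
        packages=(
            PackageEntry("a", "pypi-like", ("1.0",), (("b", "pypi-like"), ("c", "pypi-like"))),
            PackageEntry("b", "pypi-like", ("1.0",), (("d", "pypi-like"),)),
            PackageEntry("c", "pypi-like", ("1.0",), (("d", "pypi-like"),)),
            PackageEntry("d", "pypi-like", ("1.0", "2.1")),
        ),
        seed=11,
    )
    return build_mock_registry(spec)


@pytest.fixture
def diamond_backend(diamond_registry):
    return MockSandboxBackend(diamond_registry)


@pytest.fixture
def layer0():
    return LayerConfig(number=0, options={"language": "python-stack"})


@pytest.fixture
def request_a():
    return [PackageRequest("a", "pypi-like")]
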