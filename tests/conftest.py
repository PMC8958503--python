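import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hepdcl import chemlib


@pytest.fixture(scope="session")
def registry():
    return chemlib.default_blocks()


@pytest.fixture(scope="session")
def core(registry):
    core, _ = chemlib.split_registry(registry)
    return core


@pytest.fixture(scope="session")
def aldehydes(registry):
    _, alds = chemlib.split_registry(registry)
    return alds


@pytest.fixture(scope="session")
def library(core, aldehydes):
    return chemlib.enumerate_library(core, aldehydes)
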