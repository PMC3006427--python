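from __future__ import annotations

import numpy as np
import pytest

from mtphylo.nomenclature import load_nomenclature
from mtphylo.reference import load_reference
from mtphylo.variants import SequenceProfile, parse_variant


@pytest.fixture(scope="session")
def ref():
    return load_reference()


@pytest.fixture(scope="session")
def nomen():
    return load_nomenclature()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20101221)


def make_profile(sample_id: str, names: str | list[str], coverage: str = "complete", **kw):
    if isinstance(names, str):
        names = [n for n in names.split(",") if n]
    return SequenceProfile(
        sample_id,
        coverage=coverage,
        variants=frozenset(parse_variant(n) for n in names),
        **kw,
    )


@pytest.fixture
def profile_factory():
    return make_profile
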