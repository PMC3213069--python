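import pytest

from nmrmatch import MetaboliteRecord, Peak, PeakList, ReferenceLibrary


def record(rid, ppms, name=None, **meta):
    return MetaboliteRecord(
        id=rid, name=name or rid.lower(), peaks=tuple(Peak(p) for p in ppms), **meta
    )


@pytest.fixture
def toy_library():
    """Three metabolites: A(1,2,3 ppm), B(1 ppm), C(5,6 ppm)."""
    return ReferenceLibrary(
        [record("A", [1.0, 2.0, 3.0]), record("B", [1.0]), record("C", [5.0, 6.0])]
    )


@pytest.fixture
def sample_123():
    return PeakList.from_pairs([(1.0, 1.0), (2.0, 1.0), (3.0, 1.0)])
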