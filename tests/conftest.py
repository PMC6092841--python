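import pytest

from ycapture import synthio


@pytest.fixture
def small_regions() -> synthio.TargetRegions:
    """Fixed miniature target design: 3 regions, 300 bp total on a 10 kb chrY."""
    return synthio.TargetRegions("chrY", [(1000, 1100), (4000, 4150), (8000, 8050)])


@pytest.fixture
def small_profile() -> synthio.LibraryProfile:
    return synthio.LibraryProfile(
        pool_size=2000,
        endogenous_fraction=0.5,
        y_fraction_of_endogenous=0.5,
        fragment_length_mean=90.0,
        fragment_length_sd=15.0,
        min_length=30,
        reference_lengths={"chrY": 10_000, "chrX": 10_000, "autosomes": 50_000},
    )


def make_read(ref="chrY", start=0, end=50, strand="+", read_id="r0", template_id="t0"):
    return synthio.ReadRecord(read_id, template_id, ref, start, end, strand)
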