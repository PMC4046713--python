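import numpy as np
import pytest

from snvpool import SiteCounts, VariantSite


def make_site(pos: int = 100, chrom: str = "1", ref: str = "A", alt: str = "G") -> VariantSite:
    return VariantSite(chrom=chrom, pos=pos, ref=ref, alt=alt)


def make_counts(ref: int, alt: int, other: int = 0, pos: int = 100) -> SiteCounts:
    return SiteCounts(site=make_site(pos), ref_count=ref, alt_count=alt, other_count=other)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(173920)
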