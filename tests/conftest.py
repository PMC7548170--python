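import numpy as np
import pytest

from barcodescope.seqio import AlignedSeqSet, SpecimenRecord


@pytest.fixture
def small_alignment() -> AlignedSeqSet:
    return AlignedSeqSet(
        ids=("s1", "s2", "s3", "s4", "s5"),
        seqs=(
            "ACGTACGTACGT",
            "ACGTACGTACGT",
            "ACGTACGTACGT",
            "ACGAACGTACGT",
            "ACGAACGTACGT",
        ),
    )


@pytest.fixture
def located_specimens() -> list[SpecimenRecord]:
    mk = lambda i, sp, site, country, region, lat, lon: SpecimenRecord(
        seq_id=i, species=sp, site_name=site, country=country,
        region=region, lat=lat, lon=lon,
    )
    return [
        mk("s1", "spA", "north1", "Germany", "EU", 50.0, 10.0),
        mk("s2", "spA", "north2", "Germany", "EU", 52.0, 11.0),
        mk("s3", "spA", "south1", "Spain", "IB", 40.0, -3.0),
        mk("s4", "spA", "south2", "Spain", "IB", 37.0, -5.0),
        mk("s5", "spA", "italy1", "Italy", "IT", 42.0, 12.0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
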