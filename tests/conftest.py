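import numpy as np
import pytest

from netnight.io import CaptureRecord


def make_record(
    site="s1", night="n1", species="spA", time_min=30, family="Phyllostomidae",
    count=1, guild="FR",
):
    return CaptureRecord(
        dataset_id="toy", site_id=site, night_id=night, species_id=species,
        family=family, time_min=time_min, count=count, guild=guild,
    )


@pytest.fixture
def toy_records():
    """7 records over 2 nights x 3 species (grand total 7)."""
    return [
        make_record(night="n1", species="spA", time_min=30),
        make_record(night="n1", species="spA", time_min=60),
        make_record(night="n1", species="spB", time_min=300),
        make_record(night="n2", species="spA", time_min=390),
        make_record(night="n2", species="spB", time_min=600),
        make_record(night="n2", species="spC", time_min=630),
        make_record(night="n2", species="spC", time_min=690),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
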