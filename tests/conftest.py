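import pytest

from delrand import load_bsla_construct
from delrand.io_cli import packaged_region_config
from delrand.libdesign import TargetRegion, design_deletion_randomization
from delrand.screenstats import load_bsla_screening_records


@pytest.fixture(scope="session")
def bsla():
    return load_bsla_construct()


@pytest.fixture(scope="session")
def region_config():
    return packaged_region_config()


@pytest.fixture(scope="session")
def designs(bsla, region_config):
    """All six packaged deletion/randomization designs, keyed by library name."""
    out = {}
    for entry in region_config:
        region = TargetRegion.from_construct(bsla, entry["name"], entry["start"], entry["end"])
        out[entry["name"]] = design_deletion_randomization(
            region, bsla, deleted_override=entry.get("deleted_override")
        )
    return out


@pytest.fixture(scope="session")
def screening_records():
    return load_bsla_screening_records()
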