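import pytest

from hairpinsense import (
    DesignConfig,
    HairpinParams,
    build_substrate,
    design_rna_sensor,
)
from hairpinsense.simdata import TranscriptSimConfig, simulate_transcript
from hairpinsense.sitescan import scan_target


@pytest.fixture(scope="session")
def default_substrate():
    """The editing-optimal hairpin substrate (10 + 12 bp flanking the A-C)."""
    return build_substrate(HairpinParams())


@pytest.fixture(scope="session")
def model_substrate():
    """The 16-bp model substrate (7 + 9 bp)."""
    return build_substrate(HairpinParams(len_a=7, len_b=9))


@pytest.fixture(scope="session")
def planted_transcript():
    """A 200-nt transcript with one planted clean sensor site at 80."""
    return simulate_transcript(TranscriptSimConfig(seed=7, length=200, clean_site=80))


@pytest.fixture(scope="session")
def rna_sensor(planted_transcript):
    transcript, _ = planted_transcript
    site = scan_target(transcript, DesignConfig()).sites[0]
    return design_rna_sensor(transcript, site)
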