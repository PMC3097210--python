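import pytest

from chitfam.seqio import ProteinRecord, load_catalogue
from chitfam.synthetic import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def ag_catalogue():
    return load_catalogue("ag_catalogue.tsv")


@pytest.fixture(scope="session")
def nomenclature():
    return load_catalogue("nomenclature_dm_tc_ag.tsv")


@pytest.fixture(scope="session")
def family_5pct():
    """The standard benchmark family: 8 groups x 3 members at 5% divergence."""
    config = SimulationConfig(seed=42, n_groups=8, members_per_group=3, divergence=0.05)
    records, manifest = simulate_family(config)
    return config, records, manifest


@pytest.fixture(scope="session")
def family_anchors(family_5pct):
    _, _, manifest = family_5pct
    return [
        (ProteinRecord(f"anchor_{g}", seq), g)
        for g, seq in manifest.ancestor_domains.items()
    ]
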