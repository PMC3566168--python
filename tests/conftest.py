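import pytest

from metalsite import ProteinRecord, extract_sites
from metalsite.synthetic import PlantedPair, SyntheticConfig, generate


@pytest.fixture
def make_record():
    def _make(rec_id="p1", sequence="ACDEFGHIKLMNP", binding=()):
        return ProteinRecord(
            id=rec_id,
            sequence=sequence,
            binding_sites={pos: "Fe" for pos in binding},
        )

    return _make


@pytest.fixture(scope="session")
def small_planted():
    """A small strongly planted dataset shared by pipeline-level tests."""
    cfg = SyntheticConfig(
        n_proteins=12,
        length_range=(100, 160),
        n_positive_sites=25,
        n_negative_sites=75,
        planted_pairs=[PlantedPair(-4, "C", 1, "P", 0.8, 0.05)],
        pssm_signal=2.0,
        seed=7,
    )
    dataset = generate(cfg)
    sites = [
        s
        for r in dataset.records
        for s in extract_sites(r)
        if s.residue == "C"
    ]
    return dataset, sites
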