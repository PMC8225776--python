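import pytest

from threatminer import SimConfig, generate_corpus, run


@pytest.fixture(scope="session")
def sim500():
    """One 500-taxon synthetic study, shared read-only across tests."""
    return generate_corpus(SimConfig(n_taxa=500, seed=42))


@pytest.fixture(scope="session")
def result500(sim500):
    """Pipeline result for the shared 500-taxon study with oracle curation."""
    return run(sim500.records, sim500.pig_range, sim500.regions, sim500.curation)


def write_csv(path, header, rows):
    lines = [header] + [",".join(str(c) for c in row) for row in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
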