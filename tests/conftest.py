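import pytest

from phyprof import fixtures, report, simulate


@pytest.fixture(scope="session")
def euk_tree():
    return fixtures.load_tree("eukaryota")


@pytest.fixture(scope="session")
def euk_matrix():
    return fixtures.eukaryote_matrix()


@pytest.fixture(scope="session")
def combined_tree():
    return fixtures.load_tree("combined")


@pytest.fixture(scope="session")
def combined_matrix():
    return fixtures.combined_matrix()


@pytest.fixture(scope="session")
def family_profiles():
    return report.build_default_profiles()


@pytest.fixture(scope="session")
def i29_profile():
    return report.build_i29_profile()


@pytest.fixture(scope="session")
def sim_seed3():
    """Simulated content + sequences used across classification tests."""
    cfg = simulate.SimConfig(seed=3, n_leaves=25)
    content, truth, tree = simulate.simulate_content(cfg)
    records, origins = simulate.simulate_sequences(cfg, content, tree)
    return {"config": cfg, "content": content, "truth": truth,
            "tree": tree, "records": records, "origins": origins}


@pytest.fixture(scope="session")
def five_cases():
    return simulate.five_hgt_cases()
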