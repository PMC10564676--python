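import numpy as np
import pytest
from hypothesis import settings

import sogwas as sg

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_map():
    return sg.simulate_map(200, n_chrom=2, chrom_len_cm=100.0, seed=11)


@pytest.fixture(scope="session")
def founders():
    return sg.simulate_founders(40, 40, 200, divergence=0.25, seed=12)


@pytest.fixture(scope="session")
def factorial_panel(founders):
    return sg.simulate_factorial(founders, 80, seed=13)


@pytest.fixture(scope="session")
def dh_lines(factorial_panel, small_map):
    return sg.simulate_dh(factorial_panel, small_map, 100, seed=14)


@pytest.fixture(scope="session")
def diallel_panel(dh_lines):
    return sg.simulate_diallel(dh_lines, 150, seed=15)


@pytest.fixture(scope="session")
def diallel_kinships(diallel_panel):
    return sg.panel_kinships(diallel_panel)


def random_so_panel(n, m, rng, p_allele=0.5):
    """Synthetic panel with iid gametes (no linkage): alleles Bern(p),
    origins Bern(0.5).  Used for calibration tests where marker columns
    must be independent of each other and of any phenotype."""
    alleles = (rng.random((n, m, 2)) < p_allele).astype(np.uint8)
    origins = (rng.random((n, m, 2)) < 0.5).astype(np.uint8)
    return sg.PanelGenotypes(
        hybrids=[f"h{i}" for i in range(n)],
        markers=[f"m{j:05d}" for j in range(m)],
        alleles=alleles,
        origins=origins,
        design=sg.CrossDesign(kind="diallel", pairs=[]),
    )
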