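import numpy as np
import pytest

import admixclock as ac
from admixclock import hmm


@pytest.fixture(scope="session")
def recomb_map():
    return ac.generate_recomb_map(seed=11)


@pytest.fixture(scope="session")
def record():
    return ac.generate_historical_record((1775.0, 60.0), total=1e5)


@pytest.fixture(scope="session")
def scaling():
    return ac.ScalingFactor(mu=4.85e-9, g=0.067)


@pytest.fixture(scope="session")
def trajectory(record, scaling):
    return ac.generate_migration_trajectory(record, scaling)


@pytest.fixture(scope="session")
def informative_sites(recomb_map):
    """Thinned ancestry-informative panel, ~1000 sites per chromosome."""
    panel = ac.simulate_panel_freqs(30_000, F=0.3, seed=11, recomb_map=recomb_map)
    sites = hmm.select_informative_sites(panel)
    keep = []
    for sl in sites.chrom_slices().values():  # even stride across the chromosome
        keep.append(np.linspace(sl.start, sl.stop - 1, 1000).round().astype(int))
    sub = sites.sites.iloc[np.concatenate(keep)].reset_index(drop=True)
    return ac.PanelPair(sites=sub)


@pytest.fixture(scope="session")
def admixed_dataset(informative_sites, recomb_map):
    """Diploid genotypes from a known pulse (T=450, alpha=0.3, 10 diploids)."""
    geno, truth = ac.simulate_admixed_genomes(
        informative_sites, T=450.0, alpha=0.3, n_ind=10, seed=21, recomb_map=recomb_map
    )
    return geno, truth
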