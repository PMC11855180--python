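import numpy as np
import pandas as pd
import pytest

import pairkin as pk
from pairkin.genmap import Chromosome, GeneticMap
from pairkin.panel import PanelDef


@pytest.fixture(scope="session")
def gmap_default():
    return pk.build_default_map()


@pytest.fixture(scope="session")
def gmap_small():
    """Two chromosomes, 300 cM total: cheap whole-genome drops."""
    return pk.build_default_map(n_chrom=2, total_cm=300.0)


@pytest.fixture(scope="session")
def panel_small(gmap_small):
    return pk.make_fixture_panel(gmap_small, 800, seed=1, name="small")


@pytest.fixture(scope="session")
def panel_mid(gmap_default):
    """A ~10,000-marker fixture panel on the default map."""
    return pk.make_fixture_panel(gmap_default, 9618, seed=42, name="mid")


def manual_panel(positions_cm, freqs, chrom="1", length_cm=None):
    """Tiny hand-built panel + map for constructed-genotype tests."""
    positions_cm = np.asarray(positions_cm, dtype=float)
    L = float(length_cm if length_cm is not None else positions_cm[-1] + 1)
    cm = GeneticMap(
        (Chromosome(chrom, np.array([1.0, L * 1e6]), np.array([0.0, L])),)
    )
    markers = pd.DataFrame(
        {
            "chrom": chrom,
            "bp": (positions_cm * 1e6 + 1).astype(int),
            "cm": positions_cm,
            "freq": np.asarray(freqs, dtype=float),
        }
    )
    return PanelDef("manual", markers), cm


def make_obs(panel, ga, gb, true_ibd=None):
    return pk.PairObservation(
        panel=panel,
        genotypes_a=np.asarray(ga, dtype=np.int8),
        genotypes_b=np.asarray(gb, dtype=np.int8),
        true_ibd=true_ibd,
    )
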