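import numpy as np
import pandas as pd
import pytest

from allometree.io import SpecimenTable, SpeciesMeta
from allometree.tree import Phylo


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_traits():
    return ("T1", "T2", "T3", "T4")


def make_table(beta: dict, traits, n_per=20, sigma=0.0, seed=0,
               x_lo=2.0, x_hi=3.5) -> SpecimenTable:
    """Small specimen table from known zero-sum slope vectors."""
    rng = np.random.default_rng(seed)
    p = len(traits)
    c = np.linspace(2.0, 3.0, p)
    rows = []
    for sp, b in beta.items():
        b = np.asarray(b, float)
        assert abs(b.sum()) < 1e-12
        x = rng.uniform(x_lo, x_hi, n_per)
        eps = rng.normal(0, sigma, (n_per, p))
        logm = c + (1.0 + b)[None, :] * x[:, None] + eps
        for i in range(n_per):
            row = {"specimen_id": f"{sp}_{i}", "species": sp}
            row.update({t: float(np.exp(logm[i, j]))
                        for j, t in enumerate(traits)})
            rows.append(row)
    return SpecimenTable(pd.DataFrame(rows), traits)


@pytest.fixture()
def toy_table(toy_traits):
    beta = {
        "sp_a": np.array([0.2, -0.1, -0.05, -0.05]),
        "sp_b": np.array([-0.1, 0.1, 0.05, -0.05]),
        "sp_c": np.array([0.0, 0.0, 0.1, -0.1]),
    }
    return make_table(beta, toy_traits, n_per=25, sigma=0.01, seed=1)


@pytest.fixture()
def toy_meta():
    return SpeciesMeta(pd.DataFrame({
        "species": ["sp_a", "sp_b", "sp_c"],
        "partition": ["Ameridelphia", "Australidelphia", "Australidelphia"],
        "order": ["Didelphimorphia", "Dasyuromorphia", "Diprotodontia"],
        "diet": ["animalivory", "animalivory", "herbivory"],
        "body_mass": [120.0, 800.0, 5400.0],
    }))


@pytest.fixture()
def toy_tree():
    return Phylo.from_newick("((sp_a:30,sp_b:30):40,sp_c:70);")


@pytest.fixture()
def balanced6():
    return Phylo.from_newick(
        "(((A:10,B:10):20,(C:10,D:10):20):20,(E:25,F:25):25);")
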