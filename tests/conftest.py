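import numpy as np
import pandas as pd
import pytest

from aquassembly import (CommunityMatrix, SimConfig, preprocess, rarefy,
                         simulate_dataset)


@pytest.fixture
def toy_cm():
    """4 samples x 5 OTUs with one chloroplast OTU and one rare OTU."""
    data = pd.DataFrame(
        [[10, 0, 3, 2, 1],
         [8, 2, 0, 2, 1],
         [0, 12, 5, 2, 1],
         [1, 9, 4, 3, 6]],
        index=["A", "B", "C", "D"],
        columns=["otu1", "otu2", "otu3", "otu4", "otu5"],
    )
    tax = pd.Series(
        {"otu1": "Bacteria;Proteobacteria;Pseudomonas",
         "otu2": "Bacteria;Cyanobacteria;Synechococcus",
         "otu3": "Eukaryota;Chloroplast;phototroph",
         "otu4": "Bacteria;Firmicutes;Clostridium",
         "otu5": "Bacteria;Bacteroidetes;Flavobacterium"})
    return CommunityMatrix(data, tax)


@pytest.fixture
def toy_metadata():
    return pd.DataFrame(
        {"ecosystem": ["river", "lake", "lake", "lake"],
         "latitude": [43.2, 43.3, 43.25, 43.9],
         "longitude": [116.0, 116.1, 116.05, 117.2],
         "salinity": [0.21, 0.44, 6.22, 11.36]},
        index=pd.Index(["A", "B", "C", "D"], name="sample_id"))


def small_config(nu=0.5, seed=0, **kw):
    defaults = dict(n_species=150, reads_per_sample=1000,
                    samples_per_group=(4, 5, 6, 5), nu=nu, seed=seed)
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    """A fast 20-sample synthetic dataset, preprocessed and rarefied."""
    cfg = small_config(nu=0.3, seed=7)
    cm, md, truth = simulate_dataset(cfg)
    cm = preprocess(cm)
    cm = rarefy(cm, int(cm.sample_totals.min()), seed=7)
    return cm, md, truth
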