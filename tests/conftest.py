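import numpy as np
import pytest

import syntronet as sn


@pytest.fixture
def small_table() -> sn.OtuTable:
    """Hand-built 3-sample x 5-OTU table with one contaminant and one rare OTU."""
    counts = np.array(
        [
            [100, 40, 9, 3, 0],
            [80, 55, 2, 5, 1],
            [120, 30, 7, 2, 0],
        ]
    )
    lineages = (
        "Archaea;Euryarchaeota;Methanomicrobia;Methanosarcinales;ANME-2b;OTU_A",
        "Bacteria;Proteobacteria;Deltaproteobacteria;Desulfobacterales;"
        "Desulfobacteraceae;Desulfococcus;OTU_B",
        "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;"
        "Burkholderiaceae;Ralstonia;OTU_C",
        "Bacteria;Chloroflexi;Anaerolineae;Anaerolineales;Anaerolineaceae;"
        "Anaerolinea;OTU_D",
        "Bacteria;Atribacteria;JS1;o;f;g;OTU_E",
    )
    table = sn.OtuTable(
        counts=counts,
        sample_ids=("S0", "S1", "S2"),
        otu_ids=("OTU_A", "OTU_B", "OTU_C", "OTU_D", "OTU_E"),
        lineage=lineages,
        clade=("other",) * 5,
    )
    return sn.assign_clades(table)


@pytest.fixture
def random_table() -> sn.OtuTable:
    """Generated 40-sample x 30-OTU table with no planted structure."""
    return sn.gen_otu_table(sn.SimOtuConfig(n_samples=40, n_otus=30, seed=11))
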