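"""Shared fixtures: small maps, populations and architectures.

Everything is generated programmatically with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stressgate.datatypes import GeneticMap, QTLSpec, TrueArchitecture
from stressgate.simulate import make_map, simulate_phenotypes, simulate_ril_genotypes


@pytest.fixture(scope="session")
def small_map() -> GeneticMap:
    """Four chromosomes x 8 markers, 140 cM each (20 cM spacing)."""
    return make_map(4, 8, 140.0, seed=11)


@pytest.fixture(scope="session")
def two_marker_map() -> GeneticMap:
    return GeneticMap(
        pd.DataFrame(
            {
                "marker": ["left", "right"],
                "chrom": [1, 1],
                "pos_cM": [0.0, 50.0],
                "bin": ["1.00", "1.03"],
            }
        )
    )


@pytest.fixture(scope="session")
def ril_population(small_map):
    """250 RILs on the small map (no intermating)."""
    return simulate_ril_genotypes(small_map, 250, 0, seed=23)


@pytest.fixture(scope="session")
def one_qtl_arch(small_map) -> TrueArchitecture:
    marker = small_map.table.iloc[4]["marker"]  # mid chromosome 1
    return TrueArchitecture(
        qtl=(QTLSpec(marker=marker, gate="independent", effect_uv=0.6, effect_drought=0.4),),
        trait_mean=10.0,
        block_sd=0.5,
        residual_sd=1.0,
    )


@pytest.fixture(scope="session")
def one_qtl_phenotypes(ril_population, one_qtl_arch):
    return simulate_phenotypes(ril_population, one_qtl_arch, n_blocks=4, seed=37)
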