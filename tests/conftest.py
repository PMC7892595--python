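import numpy as np
import pandas as pd
import pytest

from sipdenit.chem_timeseries import ChemSeries, Phase, SupplementationEvent


def make_series(analyte, days, values, treatment="13C", replicate="1"):
    return ChemSeries(
        treatment=treatment,
        replicate=replicate,
        analyte=analyte,
        days=np.asarray(days, float),
        values=np.asarray(values, float),
    )


@pytest.fixture
def phase_i():
    return Phase("I", 0.0, 6.0)


@pytest.fixture
def table2_phase1_series(phase_i):
    """Series whose phase-I deltas equal the study's printed balances:
    111 µM acetate / 215 µM NO3-N consumed; 124 CO2-C, 2 CH4-C, 25 N2O-N,
    71 N2-N, 8 NH4-N produced (gas deltas in N-mol; molecule series halved).
    """
    return {
        "acetate": make_series("acetate", [0, 6], [111.0, 0.0]),
        "nitrate": make_series("nitrate", [0, 6], [215.0, 0.0]),
        "CO2": make_series("CO2", [0, 6], [0.0, 124.0]),
        "CH4": make_series("CH4", [0, 6], [0.0, 2.0]),
        "N2O": make_series("N2O", [0, 6], [0.0, 12.5]),
        "N2": make_series("N2", [0, 6], [0.0, 35.5]),
        "ammonium": make_series("ammonium", [0, 6], [0.0, 8.0]),
    }


def planted_fold_tables(
    fold=8.0,
    n_otus=100,
    depth=10_000,
    n_replicates=3,
    fractions_per_rep=3,
    planted_share=0.01,
    seed=0,
):
    """Heavy/light count tables with one OTU enriched ``fold``-times in the
    heavy-side composition; every replicate contributes several gradient
    fraction samples per side."""
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.full(n_otus - 1, 5.0)) * (1 - planted_share)
    light = np.concatenate([[planted_share], base])
    heavy = light.copy()
    heavy[0] *= fold
    heavy /= heavy.sum()
    n_side = n_replicates * fractions_per_rep
    h = np.vstack([rng.multinomial(depth, heavy) for _ in range(n_side)]).T
    l = np.vstack([rng.multinomial(depth, light) for _ in range(n_side)]).T
    idx = [f"OTU_{i:03d}" for i in range(n_otus)]
    return (
        pd.DataFrame(h, index=idx, columns=[f"H{i}" for i in range(n_side)]),
        pd.DataFrame(l, index=idx, columns=[f"L{i}" for i in range(n_side)]),
    )
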