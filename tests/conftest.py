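import math

import numpy as np
import pandas as pd
import pytest

from evidem_mcda import AggregatedPanel, build_core_model, load_dpp4_fixture


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()


@pytest.fixture(scope="session")
def dpp4():
    """(model, aggregated panel) for the built-in DPP-4 worked example."""
    return load_dpp4_fixture()


PRINTED_VALUES = {
    "Sitagliptin": 0.45,
    "Linagliptin": 0.44,
    "Vildagliptin": 0.43,
    "Alogliptin": 0.42,
    "Saxagliptin": 0.40,
}


def make_random_agg(rng: np.random.Generator, *, n_criteria=None,
                    n_interventions=None, with_missing=True,
                    n_panelists=6) -> AggregatedPanel:
    """A random but valid aggregated panel for property/oracle tests."""
    k = n_criteria or int(rng.integers(2, 14))
    m = n_interventions or int(rng.integers(1, 7))
    criteria = [f"c{i}" for i in range(k)]
    drugs = [f"drug_{chr(ord('A') + j)}" for j in range(m)]
    kinds = {c: ("absolute" if rng.random() < 0.5 else "relative")
             for c in criteria}

    wm, ws = {}, {}
    sm = pd.DataFrame(index=criteria, columns=drugs, dtype=float)
    ss = pd.DataFrame(index=criteria, columns=drugs, dtype=float)
    for c in criteria:
        weighted = (not with_missing) or rng.random() < 0.9
        wm[c] = float(rng.uniform(1, 5)) if weighted else math.nan
        ws[c] = float(rng.uniform(0, 1.2)) if weighted else math.nan
        scored = (not with_missing) or rng.random() < 0.85
        lo, hi = (0.0, 5.0) if kinds[c] == "absolute" else (-5.0, 5.0)
        if scored:
            sm.loc[c] = rng.uniform(lo, hi, size=m)
            ss.loc[c] = rng.uniform(0, 1.2, size=m)
            if with_missing and rng.random() < 0.1 and m > 1:
                # partially scored: still counts as unscored
                sm.loc[c, drugs[0]] = math.nan
                ss.loc[c, drugs[0]] = math.nan
        else:
            sm.loc[c] = math.nan
            ss.loc[c] = math.nan
    # guarantee at least one criterion both weighted and scored everywhere
    c0 = criteria[0]
    wm[c0] = float(rng.uniform(1, 5))
    ws[c0] = float(rng.uniform(0, 1.2))
    lo, hi = (0.0, 5.0) if kinds[c0] == "absolute" else (-5.0, 5.0)
    sm.loc[c0] = rng.uniform(lo, hi, size=m)
    ss.loc[c0] = rng.uniform(0, 1.2, size=m)

    return AggregatedPanel(
        criteria=tuple(criteria), interventions=tuple(drugs),
        weight_mean=pd.Series(wm), weight_sd=pd.Series(ws),
        score_mean=sm, score_sd=ss,
        n_panelists=n_panelists, scale_kinds=kinds,
    )


@pytest.fixture
def random_agg_factory():
    return make_random_agg
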