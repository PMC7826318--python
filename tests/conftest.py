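import numpy as np
import pytest

import ldefit as lf


@pytest.fixture(scope="session")
def small_p2_panel():
    """Two-series, 8-person, 40-day panel at moderate noise; no missing."""
    cfg = lf.SimConfig(
        params=lf.DLOParams(eta=-0.02, zeta=-0.04),
        n_persons=8, n_occasions=40, n_series=2,
        series_loadings=(1.0, 1.2), noise_sd=(0.3, 0.3),
        equilibrium_mean=10.0, equilibrium_sd=3.0,
        init_pos_sd=2.0, init_vel_sd=0.25,
        missing_rate=0.0, seed=42,
    )
    return lf.simulate_panel(cfg), cfg


@pytest.fixture(scope="session")
def small_fits(small_p2_panel):
    """SOLDE and FOLDE fitted to the small panel at D=5."""
    panel, _ = small_p2_panel
    tde = lf.embed_panel(panel, 5)
    opts = lf.FitOptions(seed=1, compute_se=False)
    solde = lf.LDEModel(tde, order=2).fit(opts)
    folde = lf.LDEModel(tde, order=4).fit(opts)
    return solde, folde


@pytest.fixture(scope="session")
def tiny_p1_panel():
    """Univariate 12-person, 50-day panel; no missing cells."""
    cfg = lf.SimConfig(
        params=lf.DLOParams(eta=-0.03, zeta=-0.05),
        n_persons=12, n_occasions=50, n_series=1,
        series_loadings=(1.0,), noise_sd=(0.4,),
        equilibrium_mean=5.0, equilibrium_sd=2.0,
        init_pos_sd=2.0, init_vel_sd=0.3,
        missing_rate=0.0, seed=7,
    )
    return lf.simulate_panel(cfg), cfg


def random_theta(spec, rng):
    """A random valid natural-scale parameter vector for property tests."""
    p = spec.P
    vals = [rng.uniform(-0.5, -0.001), rng.uniform(-0.3, 0.0)]
    vals += list(rng.uniform(0.5, 1.5, p - 1))
    v_f, v_df = rng.uniform(0.5, 3.0), rng.uniform(0.05, 0.5)
    c = rng.uniform(-0.8, 0.8) * np.sqrt(v_f * v_df)
    vals += [v_f, v_df, c]
    vals += list(rng.uniform(0.001, 0.1, spec.n_resid))
    vals += list(rng.uniform(0.2, 2.0, p))
    vals += list(rng.normal(0.0, 3.0, spec.n_persons))
    return lf.ParamVector(spec, np.array(vals))
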