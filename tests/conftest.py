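"""Shared fixtures: small simulated studies reused across the suite.

The heavier planted-effect studies are session-scoped so that recovery
checks and acceptance tests share one simulation each.
"""

import warnings

import pandas as pd
import pytest

from epipair import SimulationConfig, simulate_study
from epipair import dmp as dmp_mod


@pytest.fixture(scope="session")
def small_study():
    """Tiny default-effect study for structural tests."""
    cfg = SimulationConfig(n_pairs=10, n_probes=600, n_genes=80, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(cfg)


@pytest.fixture(scope="session")
def dmp_recovery_study():
    """Planted DMP/DEG study: Δβ = 0.3, 30 pairs, no hydroxymethylation.

    Hydroxymethylation transitions are genuine BS-visible methylation
    changes, so they are disabled here to keep the planted-DMP truth the
    only source of differential methylation.
    """
    cfg = SimulationConfig(
        n_pairs=30, n_probes=3000, n_genes=300, dmp_fraction=0.05,
        hyper_fraction_among_dmps=0.8, delta_beta_effect=0.3,
        hmc_fraction=0.0, deg_fraction=0.1, corr_dyad_fraction=0.0,
        log_fc_effect=1.5, beta_dispersion=50.0, seed=11,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(cfg)


@pytest.fixture(scope="session")
def dyad_recovery_study():
    """Planted dyad study: ρ = 0.9 coupling, 50 pairs."""
    cfg = SimulationConfig(
        n_pairs=50, n_probes=3000, n_genes=300, dmp_fraction=0.05,
        hyper_fraction_among_dmps=0.8, delta_beta_effect=0.3,
        hmc_fraction=0.0, deg_fraction=0.05, corr_dyad_fraction=0.1,
        rho_effect=0.9, beta_dispersion=50.0, seed=21,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(cfg)


@pytest.fixture(scope="session")
def hmc_recovery_study():
    """Planted transition study: mix (0.35, 0.05, 0.35, 0.25), 20 pairs,
    low noise."""
    cfg = SimulationConfig(
        n_pairs=20, n_probes=3000, n_genes=300, dmp_fraction=0.0,
        delta_beta_effect=0.0, hmc_fraction=0.05,
        transition_mix=(0.35, 0.05, 0.35, 0.25), beta_dispersion=200.0,
        deg_fraction=0.0, corr_dyad_fraction=0.0, seed=7,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(cfg)


@pytest.fixture(scope="session")
def called_dmps(dmp_recovery_study):
    st = dmp_recovery_study
    tested = dmp_mod.test_dmps(st.beta_bs_hcc, st.beta_bs_ntl,
                               pairing=st.sheet)
    called = dmp_mod.call_dmps(tested)
    return dmp_mod.apply_stringent_filters(called, st.beta_bs_hcc,
                                           st.beta_bs_ntl)


def make_reference_sheet():
    """Pair-level cohort with the reference study's printed margins.

    74 pairs: 39 aged <= 44 and 35 older; HBV DNA positive in 36 of the
    younger and 28 of the older stratum; cirrhosis absent in the young and
    present in 4 of the old stratum.
    """
    rows = []
    for i in range(74):
        young = i < 39
        age = (25 + i % 10) if young else (55 + i % 10)
        hbv = (i < 36) if young else (i - 39 < 28)
        cirr = False if young else (i - 39 < 4)
        pair = f"P{i + 1:03d}"
        for tissue in ("HCC", "NTL"):
            rows.append({
                "sample_id": f"{pair}_{tissue}", "pair_id": pair,
                "tissue": tissue, "age": age, "sex": "M" if i % 3 else "F",
                "hbv_positive": hbv, "cirrhosis": cirr,
                "afp": 500.0 + 10.0 * i, "tumor_size": 8.0 + i % 5,
            })
    return pd.DataFrame(rows)
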