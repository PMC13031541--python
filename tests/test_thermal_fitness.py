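import numpy as np
import pandas as pd
import pytest

from invclines.synthetic_data import simulate_viability_experiment
from invclines.thermal_fitness import (filter_low_viability,
                                       fit_quadratic_tpc, thermal_traits,
                                       viability_deviance_analysis)

# the quadratic used throughout: peak 0.26 at 20 C, roots ~14.9 / ~25.1
A, B, C = -0.01, 0.4, -3.74


def _exact_table(temps=(16.0, 18.0, 20.0, 22.0, 24.0)):
    t = np.asarray(temps)
    y = A * t**2 + B * t + C
    return pd.DataFrame({"temperature": t, "eggs": 1000,
                         "adults": 1000 * y})


def test_noiseless_quadratic_recovered_to_machine_precision():
    fit = fit_quadratic_tpc(_exact_table())
    assert fit.a == pytest.approx(A, rel=1e-9)
    assert fit.b == pytest.approx(B, rel=1e-9)
    assert fit.c == pytest.approx(C, rel=1e-9)
    assert fit.topt == pytest.approx(20.0, rel=1e-9)
    assert fit.rmax == pytest.approx(0.26, rel=1e-9)
    assert fit.concave


def test_derived_traits_match_fine_grid_search():
    traits = thermal_traits(A, B, C)
    grid = np.arange(0.0, 40.0, 0.001)
    y = A * grid**2 + B * grid + C
    pos = grid[y > 0]
    assert traits["topt"] == pytest.approx(grid[np.argmax(y)], abs=0.001)
    assert traits["rmax"] == pytest.approx(y.max(), abs=1e-5)
    assert traits["ctmin"] == pytest.approx(pos.min(), abs=0.002)
    assert traits["ctmax"] == pytest.approx(pos.max(), abs=0.002)
    assert traits["tolerance"] == pytest.approx(pos.max() - pos.min(),
                                                abs=0.004)
    broad = grid[y >= 0.8 * y.max()]
    assert traits["breadth"] == pytest.approx(broad.max() - broad.min(),
                                              abs=0.004)
    assert traits["breadth"] <= traits["tolerance"]


def test_temperature_shift_moves_only_location_traits():
    base = fit_quadratic_tpc(_exact_table())
    delta = 7.5
    shifted_tbl = _exact_table()
    shifted_tbl["temperature"] += delta
    shifted = fit_quadratic_tpc(shifted_tbl)
    assert shifted.topt == pytest.approx(base.topt + delta, rel=1e-6)
    assert shifted.ctmin == pytest.approx(base.ctmin + delta, rel=1e-6)
    assert shifted.ctmax == pytest.approx(base.ctmax + delta, rel=1e-6)
    assert shifted.rmax == pytest.approx(base.rmax, rel=1e-6)
    assert shifted.tolerance == pytest.approx(base.tolerance, rel=1e-6)
    assert shifted.breadth == pytest.approx(base.breadth, rel=1e-6)


def test_non_concave_fit_flags_traits_undefined():
    t = np.array([10.0, 20.0, 30.0])
    tbl = pd.DataFrame({"temperature": t, "eggs": 100,
                        "adults": [90, 10, 90]})
    fit = fit_quadratic_tpc(tbl)
    assert not fit.concave
    assert fit.topt is None and fit.rmax is None and fit.breadth is None


def test_needs_three_temperatures():
    tbl = pd.DataFrame({"temperature": [10.0, 20.0], "eggs": 10,
                        "adults": [1, 2]})
    with pytest.raises(ValueError):
        fit_quadratic_tpc(tbl)


def test_low_viability_temperatures_are_filtered_out():
    # 17/20/23 C sit well inside the curve's positive branch (>= 0.17)
    good = simulate_viability_experiment(A, B, C, [17, 20, 23], seed=1)
    cold = simulate_viability_experiment(0, 0, 0.01, [10], seed=2)
    filtered = filter_low_viability(pd.concat([good, cold]))
    assert 10.0 not in filtered["temperature"].unique()
    assert set(filtered["temperature"]) == {17.0, 20.0, 23.0}


def _four_line_experiment(seed, flip=0.08):
    """SS outperforms NN in America, the reverse in Europe."""
    tabs = []
    for i, (kar, cont, shift) in enumerate([
            ("SS", "America", flip), ("NN", "America", -flip),
            ("SS", "Europe", -flip), ("NN", "Europe", flip)]):
        tabs.append(simulate_viability_experiment(
            A, B, C + shift, [15, 20, 25, 30], seed=seed * 13 + i,
            line=f"{kar}-{cont}", karyotype=kar, continent=cont))
    return pd.concat(tabs, ignore_index=True)


def test_opposite_sign_interaction_is_detected():
    hits = 0
    for seed in range(8):
        res = viability_deviance_analysis(_four_line_experiment(seed))
        row = res.table.set_index("term").loc["karyotype:continent"]
        hits += row["p_value"] < 0.01
        assert row["df"] == 1
    assert hits >= 7


def test_no_karyotype_effect_keeps_type_one_error_low():
    hits = 0
    for seed in range(30):
        res = viability_deviance_analysis(_four_line_experiment(seed, flip=0.0))
        row = res.table.set_index("term").loc["karyotype"]
        hits += row["p_value"] < 0.05
    # P(X > 7 | n=30, p=0.05) < 1e-3
    assert hits <= 7


def test_single_factor_analysis_reduces_to_a_plain_lrt():
    import statsmodels.api as sm
    tbl = _four_line_experiment(3)
    res = viability_deviance_analysis(tbl, factors=("karyotype",),
                                      interactions=False)
    endog = np.column_stack([tbl["adults"], tbl["eggs"] - tbl["adults"]])
    x = (tbl["karyotype"] == "SS").astype(float).to_numpy()
    full = sm.GLM(endog, sm.add_constant(x),
                  family=sm.families.Binomial()).fit()
    lrt = full.null_deviance - full.deviance
    assert res.table.loc[0, "chi2"] == pytest.approx(lrt, rel=1e-8)


def test_deviance_never_increases_with_added_terms():
    tbl = _four_line_experiment(5)
    mains = viability_deviance_analysis(tbl, interactions=False)
    full = viability_deviance_analysis(tbl, interactions=True)
    assert full.residual_deviance <= mains.residual_deviance + 1e-9
    assert 0 <= full.deviance_r2 <= 1


def test_stochastic_parameter_recovery_is_unbiased():
    """Median recovered Topt over replicate experiments stays near truth.

    Assay temperatures sit inside the curve's positive branch so the
    binomial success probability equals the quadratic (no clipping bias).
    """
    topts, amps = [], []
    for seed in range(20):
        tbl = simulate_viability_experiment(A, B, C, [16, 18, 20, 22, 24],
                                            seed=500 + seed)
        fit = fit_quadratic_tpc(tbl)
        if fit.concave:
            topts.append(fit.topt)
            amps.append(fit.a)
    assert len(topts) >= 18
    assert np.median(np.abs(np.array(topts) - 20.0)) < 0.5
    assert np.median(np.abs(np.array(amps) - A)) < 0.5 * abs(A)
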