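import numpy as np
import pytest

from lipotherm import fit_vant_hoff, generate_cohort, gibbs_free_energy
from lipotherm.exceptions import AmbiguousSeriesError, InsufficientDataError, LipothermError
from lipotherm.thermodynamics import GAS_CONSTANT, VantHoffModel, VantHoffResult

from conftest import make_series

T_GRID = np.array([278.15, 288.15, 298.15, 308.15, 318.15])


def _series_from_line(slope, intercept, cid="A", mod="MeOH", phi=0.15, temps=T_GRID):
    k = np.exp(slope / temps + intercept)
    return make_series(cid, mod, phi, temps, k)


def test_constructed_line_gives_exact_enthalpy_entropy():
    vh = fit_vant_hoff(_series_from_line(1000.0, -1.0))
    assert vh.dH == pytest.approx(-8314.0, rel=1e-12)
    assert vh.dS_star == pytest.approx(-8.314, rel=1e-12)
    assert vh.fit.r2 == 1.0
    assert vh.linear_ok


@pytest.mark.parametrize("dH", [-15e3, -8e3, 5e3])
@pytest.mark.parametrize("c", [-3.0, 0.0, 4.2])
def test_enthalpy_recovered_for_any_intercept(dH, c):
    vh = fit_vant_hoff(_series_from_line(-dH / GAS_CONSTANT, c))
    assert vh.dH == pytest.approx(dH, rel=1e-10)
    assert vh.dS_star == pytest.approx(GAS_CONSTANT * c, rel=1e-10)


def test_zero_noise_cohort_recovers_truth():
    measurements, truth = generate_cohort(noise_sd=0.0, seed=5)
    series = measurements[measurements["phi"] == truth.phi_ref]
    results = VantHoffModel(series).fit()
    for r in results.results:
        assert r.dH == pytest.approx(truth.param(r.compound_id, f"dH_{r.modifier}"), rel=1e-9)
        assert r.dS_star == pytest.approx(
            truth.param(r.compound_id, f"dS_star_{r.modifier}"), rel=1e-9
        )


def test_curved_series_fails_linearity_gate():
    inv_t = 1.0 / T_GRID
    ln_k = 1e7 * (inv_t - inv_t.mean()) ** 2 + 1.0  # curvature, no linear trend
    vh = fit_vant_hoff(make_series("A", "ACN", 0.15, T_GRID, np.exp(ln_k)))
    assert not vh.linear_ok
    assert vh.fit.r2 < 0.9


def test_gate_failures_raise_unless_overridden():
    inv_t = 1.0 / T_GRID
    vh = fit_vant_hoff(make_series("A", "ACN", 0.15, T_GRID,
                                   np.exp(1e7 * (inv_t - inv_t.mean()) ** 2)))
    with pytest.raises(LipothermError, match="linearity gate"):
        gibbs_free_energy(vh)
    with pytest.warns(UserWarning, match="non-linear"):
        g = gibbs_free_energy(vh, allow_nonlinear=True)
    assert g.dG == pytest.approx(vh.dH - 293.15 * vh.dS_star)


def test_gibbs_arithmetic_and_zero_t_limit():
    vh = VantHoffResult(
        compound_id="A", modifier="MeOH", phi=0.15, dH=-10e3, dS_star=-10.0,
        fit=fit_vant_hoff(_series_from_line(1000.0, 0.0)).fit, linear_ok=True,
    )
    assert gibbs_free_energy(vh, t_ref=300.0).dG == pytest.approx(-7e3)
    assert gibbs_free_energy(vh, t_ref=0.0).dG == pytest.approx(vh.dH)
    with pytest.raises(LipothermError):
        gibbs_free_energy(vh, t_ref=-1.0)


def test_gibbs_linear_in_reference_temperature(thermo_results):
    r = thermo_results.results[0]
    t = np.array([280.0, 290.0, 300.0, 310.0])
    dg = np.array([gibbs_free_energy(r, t_ref=ti).dG for ti in t])
    slopes = np.diff(dg) / np.diff(t)
    assert np.allclose(slopes, -r.dS_star, rtol=1e-12)


def test_entropy_differences_cancel_phase_ratio_bias():
    """Scaling every k by a constant (an ln PhaseRatio shift) moves each dS*
    but leaves pairwise dS* differences untouched."""
    s1 = _series_from_line(1500.0, 2.0, cid="A")
    s2 = _series_from_line(1900.0, 1.2, cid="B")
    d_before = fit_vant_hoff(s1).dS_star - fit_vant_hoff(s2).dS_star
    scale = 7.3
    s1["k"] *= scale
    s2["k"] *= scale
    a, b = fit_vant_hoff(s1), fit_vant_hoff(s2)
    assert a.dS_star - b.dS_star == pytest.approx(d_before, rel=1e-9)
    assert a.dS_star != pytest.approx(d_before)  # individual values did move


def test_series_validation_errors():
    with pytest.raises(AmbiguousSeriesError):
        fit_vant_hoff(make_series("A", "MeOH", [0.1, 0.15, 0.15, 0.15, 0.15],
                                  T_GRID, np.ones(5)))
    with pytest.raises(InsufficientDataError):
        fit_vant_hoff(make_series("A", "MeOH", 0.15, [280.0, 290.0, 300.0], [1, 2, 3]))
    with pytest.raises(InsufficientDataError, match="span"):
        fit_vant_hoff(make_series("A", "MeOH", 0.15,
                                  [290.0, 295.0, 300.0, 305.0], [1, 2, 3, 4]))
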