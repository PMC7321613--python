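import numpy as np
import pandas as pd
import pytest

from lipotherm import generate_activity, generate_cohort, generate_descriptors
from lipotherm.correlation import pairwise_r2
from lipotherm.lipophilicity import SoczewinskiModel
from lipotherm.selectivity import SelectivityModel
from lipotherm.thermodynamics import VantHoffModel


def test_regeneration_is_byte_identical():
    m1, t1 = generate_cohort(seed=11)
    m2, t2 = generate_cohort(seed=11)
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(t1.table, t2.table)
    m3, _ = generate_cohort(seed=12)
    assert not m1["k"].equals(m3["k"])


def test_measurement_keys_unique_and_k_positive():
    m, _ = generate_cohort(seed=2)
    assert (m["k"] > 0).all()
    assert not m[["compound_id", "modifier", "phi", "temperature"]].duplicated().any()


def test_truth_invariants():
    _, truth = generate_cohort(seed=3)
    for mod in ("MeOH", "ACN"):
        t = truth.table
        assert np.allclose(t[f"phi0_{mod}"], -t[f"log_kw_{mod}"] / t[f"S_{mod}"])
        assert (t[f"S_{mod}"] < 0).all()
        # anchored entropy: dG = dH - T dS* holds by construction
        assert np.allclose(t[f"dG_{mod}"], t[f"dH_{mod}"] - truth.t_ref * t[f"dS_star_{mod}"])


def test_full_zero_noise_round_trip_recovers_every_parameter():
    measurements, truth = generate_cohort(noise_sd=0.0, seed=9)
    iso = measurements[measurements["temperature"] == truth.t_ref]
    vh = measurements[measurements["phi"] == truth.phi_ref]
    lipo = SoczewinskiModel(iso).fit()
    thermo = VantHoffModel(vh).fit()
    sel = SelectivityModel(vh, truth.pairs).fit()
    for ix in lipo.indices:
        assert ix.S == pytest.approx(truth.param(ix.compound_id, f"S_{ix.modifier}"), rel=1e-9)
    for r in thermo.results:
        assert r.dH == pytest.approx(truth.param(r.compound_id, f"dH_{r.modifier}"), rel=1e-9)
    for s in sel.results:
        expected = truth.param(s.pair.id_high, f"dH_{s.modifier}") - truth.param(
            s.pair.id_low, f"dH_{s.modifier}"
        )
        assert s.dHd == pytest.approx(expected, rel=1e-9)
        assert s.fit.r2 == pytest.approx(1.0)


def test_descriptor_stream_isolated_from_retention():
    m1, t1 = generate_cohort(seed=21)
    d_a = generate_descriptors(t1, seed=100)
    d_b = generate_descriptors(t1, seed=101)
    m2, _ = generate_cohort(seed=21)
    pd.testing.assert_frame_equal(m1, m2)  # descriptor draws never touch retention
    assert not d_a.equals(d_b)
    a1 = generate_activity(t1, seed=55)
    a2 = generate_activity(t1, seed=55)
    pd.testing.assert_frame_equal(a1, a2)


def test_descriptor_target_r2_exact_and_null_extremes():
    _, truth = generate_cohort(seed=5)
    exact = generate_descriptors(truth, target_r2={"d": 1.0}, seed=0)
    r2, _ = pairwise_r2(exact["d"], truth.table["dG_MeOH"])
    assert r2 == pytest.approx(1.0)
    realized = [
        pairwise_r2(
            generate_descriptors(truth, target_r2={"d": 0.0}, seed=s)["d"],
            truth.table["dG_MeOH"],
        )[0]
        for s in range(200)
    ]
    assert np.mean(realized) == pytest.approx(1.0 / 13, abs=0.02)  # null E[r2]=1/(n-1)


def test_descriptor_target_r2_calibrated_in_expectation():
    _, truth = generate_cohort(seed=5)
    realized = [
        pairwise_r2(
            generate_descriptors(truth, target_r2={"d": 0.86}, seed=s)["d"],
            truth.table["dG_MeOH"],
        )[0]
        for s in range(300)
    ]
    assert np.mean(realized) == pytest.approx(0.86, abs=0.03)


def test_activity_zero_variance_components_collapse_to_medians():
    _, truth = generate_cohort(seed=6)
    act = generate_activity(
        truth,
        mixture={"active": {"median": 100.0, "sigma": 0.0},
                 "inactive": {"median": 600.0, "sigma": 0.0}},
        seed=0,
    )
    assert set(np.round(act["ed50"], 9)) <= {100.0, 600.0}
    assert (act.loc[act["class_label"] == "active", "ed50"] == 100.0).all()


def test_activity_threshold_recovered_between_modes():
    from lipotherm import estimate_threshold

    hits = 0
    for seed in range(30):
        _, truth = generate_cohort(n_compounds=40, seed=seed)
        act = generate_activity(truth, seed=seed)
        if act["class_label"].nunique() < 2:
            continue
        thr = estimate_threshold(act["ed50"])
        lo = act.loc[act["class_label"] == "active", "ed50"].max()
        hi = act.loc[act["class_label"] == "inactive", "ed50"].min()
        hits += min(lo, hi) < thr < max(lo, hi) or (lo < thr < hi)
    assert hits >= 27


def test_degenerate_grids_rejected():
    with pytest.raises(ValueError):
        generate_cohort(phi_grids={"MeOH": (0.1, 0.1, 0.1), "ACN": (0.05, 0.1, 0.2)})
    with pytest.raises(ValueError):
        generate_cohort(t_grid=(278.15, 288.15, 298.15))
    with pytest.raises(ValueError):
        generate_cohort(noise_sd=-0.1)
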