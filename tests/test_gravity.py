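"""Two-way demeaning, gravity estimation, and coefficient recovery."""

import numpy as np
import pandas as pd
import pytest

from hospchoice import FlowTable, double_demean, fit_all, fit_gravity
from hospchoice.geo import DistanceMatrix
from hospchoice.gravity import DegenerateRegressorError, GravityChoiceModel

from conftest import dummy_ols_slope, random_panel


def test_balanced_grid_additive_values_demean_to_zero():
    # y = row effect + column effect exactly
    y = [1.0, 2.0, 3.0, 4.0]
    origins = ["a", "a", "b", "b"]
    dests = ["u", "v", "u", "v"]
    demeaned, _, _, n_iter = double_demean(y, origins, dests)
    assert np.allclose(demeaned, 0.0, atol=1e-12)
    # one working pass plus one confirming pass on a balanced grid
    assert n_iter <= 2


def test_constant_values_demean_to_zero():
    demeaned, _, _, _ = double_demean([5.0] * 6, list("aabbcc"), list("uvuvuv"))
    assert np.allclose(demeaned, 0.0, atol=1e-12)


def test_balanced_grid_group_means_vanish_after_demeaning(rng):
    df = random_panel(rng, n_origins=6, n_dests=4, fill=1.0)
    demeaned, _, _, _ = double_demean(df["y"], df["origin"], df["dest"], tol=1e-12)
    out = df.assign(v=demeaned)
    assert out.groupby("origin")["v"].mean().abs().max() < 1e-10
    assert out.groupby("dest")["v"].mean().abs().max() < 1e-10


def test_too_few_groups_is_an_error():
    with pytest.raises(ValueError, match="origins"):
        double_demean([1.0, 2.0], ["a", "a"], ["u", "v"])


@pytest.mark.parametrize("weighted", [False, True])
def test_demeaned_slope_equals_dummy_variable_ols(rng, weighted):
    """Within-estimator slope == explicit two-way indicator regression."""
    for _ in range(10):
        df = random_panel(rng)
        w = rng.integers(1, 20, size=len(df)).astype(float) if weighted else None
        yd, _, _, _ = double_demean(df["y"], df["origin"], df["dest"], weights=w)
        xd, _, _, _ = double_demean(df["x"], df["origin"], df["dest"], weights=w)
        ww = np.ones(len(df)) if w is None else w
        slope = float((ww * xd) @ yd) / float((ww * xd) @ xd)
        assert slope == pytest.approx(dummy_ols_slope(df, weights=w), abs=1e-6)


def _flow_fixture(rng, beta=-1.5, n_origins=30, n_dests=8, scale=2000.0):
    """Flows generated exactly as T = round(exp(a_i + b_j + beta*log d))."""
    zips = [f"{i + 1:05d}" for i in range(n_origins)]
    hosps = [f"H{j}" for j in range(n_dests)]
    d = np.exp(rng.uniform(0.5, 4.0, size=(n_origins, n_dests)))
    a = rng.normal(np.log(scale), 0.3, size=n_origins)
    b = rng.normal(0.0, 0.8, size=n_dests)
    t = np.exp(a[:, None] + b[None, :] + beta * np.log(d))
    counts = np.maximum(np.rint(t), 1.0)
    entries = pd.DataFrame(
        [
            (zips[i], hosps[j], int(counts[i, j]))
            for i in range(n_origins)
            for j in range(n_dests)
        ],
        columns=["origin_zip", "hospital_id", "count"],
    )
    dm = DistanceMatrix(zips, hosps, d, floor_miles=0.0, n_floored=0)
    hospitals = pd.DataFrame(
        {
            "zip": [zips[0]] * n_dests,
            "state": ["AA"] * n_dests,
            "med_school": rng.random(n_dests) < 0.5,
            "rural": rng.random(n_dests) < 0.5,
            "coc": rng.random(n_dests) < 0.5,
            "centralized": rng.random(n_dests) < 0.5,
            "volume": counts.sum(axis=0).astype(int),
        },
        index=pd.Index(hosps, name="hospital_id"),
    )
    return FlowTable(entries), dm, hospitals


def test_recovers_distance_elasticity_from_self_consistent_flows(rng):
    ft, dm, hosp = _flow_fixture(rng, beta=-1.5)
    fit = fit_gravity(ft, dm, hosp, model_spec=1)
    # rounding to integers is the only perturbation at counts ~2000
    assert fit.beta_distance == pytest.approx(-1.5, abs=0.01)
    assert fit.converged


def test_distance_free_flows_give_near_zero_elasticity(rng):
    ft, dm, hosp = _flow_fixture(rng, beta=0.0)
    fit = fit_gravity(ft, dm, hosp, model_spec=1)
    assert fit.beta_distance == pytest.approx(0.0, abs=0.01)


def test_spec3_with_constant_covariates_is_degenerate(rng):
    ft, dm, hosp = _flow_fixture(rng)
    hosp[["med_school", "rural", "coc", "centralized"]] = False
    with pytest.raises(DegenerateRegressorError):
        fit_gravity(ft, dm, hosp, model_spec=3)


def test_scale_equivariance_of_distance_elasticity(rng):
    ft, dm, hosp = _flow_fixture(rng)
    fit1 = fit_gravity(ft, dm, hosp, model_spec=1)
    dm2 = DistanceMatrix(
        dm.origin_ids, dm.destination_ids, dm.values * 7.3, dm.floor_miles, 0
    )
    fit2 = fit_gravity(ft, dm2, hosp, model_spec=1)
    assert fit1.beta_distance == pytest.approx(fit2.beta_distance, abs=1e-9)


def test_stage2_weighted_residuals_orthogonal_to_regressors(rng):
    ft, dm, hosp = _flow_fixture(rng)
    fit = fit_gravity(ft, dm, hosp, model_spec=3)
    resid = fit.stage2_residuals
    w = (
        ft.entries.groupby("hospital_id")["origin_zip"].nunique().loc[resid.index].to_numpy(float)
    )
    design = pd.DataFrame({"log_volume": np.log(hosp.loc[resid.index, "volume"].astype(float))})
    design = pd.concat([design, hosp.loc[resid.index, ["med_school", "rural", "coc", "centralized"]].astype(float)], axis=1)
    for col in design.columns:
        assert abs(float((w * resid.to_numpy()) @ design[col].to_numpy())) < 1e-8 * w.sum()


def test_recovered_effects_leave_orthogonal_residuals(rng):
    """Stage-1 residuals have (count-weighted) zero group means and are
    orthogonal to the demeaned distance regressor — the normal equations of
    the two-way fixed-effects fit."""
    ft, dm, hosp = _flow_fixture(rng)
    fit = fit_gravity(ft, dm, hosp, model_spec=2)
    e = ft.entries
    x = np.log([dm.lookup(o, h) for o, h in zip(e["origin_zip"], e["hospital_id"])])
    pred = (
        fit.origin_effects.loc[e["origin_zip"]].to_numpy()
        + fit.destination_effects.loc[e["hospital_id"]].to_numpy()
        + fit.beta_distance * x
    )
    resid = np.log(e["count"].to_numpy(float)) - pred
    w = e["count"].to_numpy(float)
    out = e.assign(wr=w * resid, w=w)
    for key in ("origin_zip", "hospital_id"):
        grouped = out.groupby(key)
        means = grouped["wr"].sum() / grouped["w"].sum()
        assert means.abs().max() < 1e-8
    xd, _, _, _ = double_demean(x, e["origin_zip"], e["hospital_id"], weights=w)
    assert abs(float((w * resid) @ xd)) < 1e-8 * w.sum()
    # residual_sd summarises these residuals on the weighted scale
    assert fit.residual_sd == pytest.approx(float(np.sqrt(np.average(resid**2, weights=w))))


def test_estimator_is_sklearn_compatible(rng):
    ft, dm, hosp = _flow_fixture(rng)
    est = GravityChoiceModel(model_spec=2)
    assert est.get_params()["model_spec"] == 2
    est.set_params(model_spec=1)
    est.fit(ft, dm, hosp)
    assert est.beta_distance_ < 0
    clone_params = GravityChoiceModel(**est.get_params()).get_params()
    assert clone_params == est.get_params()


def test_fit_all_strata_bookkeeping(small_market, small_tables):
    patients, hosp, centroids, distances = small_tables
    from hospchoice import aggregate_flows

    ft = aggregate_flows(patients)
    fits = fit_all(ft, distances, hosp, centroids, specs=(1, 2), strata=None)
    states = sorted(small_market.hospitals["state"].unique())
    assert set(fits) == {"overall"} | set(states)
    for stratum in fits:
        assert set(fits[stratum]) == {1, 2}


def test_single_state_overall_equals_state_fit(rng):
    ft, dm, hosp = _flow_fixture(rng)
    centroids = pd.DataFrame(
        {"lat": 40.0, "lon": -75.0, "state": "AA"}, index=pd.Index(dm.origin_ids, name="zip")
    )
    fits = fit_all(ft, dm, hosp, centroids, specs=(1, 2))
    assert fits["overall"][1].beta_distance == pytest.approx(
        fits["AA"][1].beta_distance, abs=1e-12
    )
    assert fits["overall"][2].beta_log_volume == pytest.approx(
        fits["AA"][2].beta_log_volume, abs=1e-12
    )


def test_state_specific_elasticities_recovered_separately(rng):
    fta, dma, hospa = _flow_fixture(rng, beta=-2.0)
    ftb, dmb, hospb = _flow_fixture(rng, beta=-1.0)
    # relabel B-state ids to keep the two markets disjoint
    ftb = FlowTable(
        ftb.entries.assign(
            origin_zip="B" + ftb.entries["origin_zip"],
            hospital_id="B" + ftb.entries["hospital_id"],
        )
    )
    fit_a = fit_gravity(fta, dma, hospa, model_spec=1)
    dmb2 = DistanceMatrix(
        ["B" + z for z in dmb.origin_ids], ["B" + h for h in dmb.destination_ids],
        dmb.values, dmb.floor_miles, 0,
    )
    hospb2 = hospb.set_index("B" + hospb.index.astype(str))
    fit_b = fit_gravity(ftb, dmb2, hospb2, model_spec=1)
    assert fit_a.beta_distance == pytest.approx(-2.0, abs=0.02)
    assert fit_b.beta_distance == pytest.approx(-1.0, abs=0.02)
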