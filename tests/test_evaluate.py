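"""Accuracy metrics, sufficiency classes, travel bias, and subgroup tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hospchoice import classify_sufficiency, subgroup_table, topk_accuracy, travel_bias
from hospchoice.evaluate import SUFFICIENCY_CLASSES, correctness, sufficiency_counts
from hospchoice.geo import DistanceMatrix


def _preds(rankings):
    """rankings: dict patient -> ordered hospital list."""
    rows = [
        (pid, r, h)
        for pid, hs in rankings.items()
        for r, h in enumerate(hs, start=1)
    ]
    return pd.DataFrame(rows, columns=["patient_id", "rank", "hospital_id"])


def test_perfect_predictions_have_accuracy_one():
    obs = pd.Series({"P1": "H1", "P2": "H2"})
    preds = _preds({"P1": ["H1", "H2"], "P2": ["H2", "H1"]})
    rep = topk_accuracy(preds, obs, ks=(1, 2))
    assert (rep["accuracy"] == 1.0).all()


def test_observed_outside_candidates_gives_zero_accuracy():
    obs = pd.Series({"P1": "H9", "P2": "H9"})
    preds = _preds({"P1": ["H1", "H2"], "P2": ["H2", "H1"]})
    rep = topk_accuracy(preds, obs, ks=(1, 2))
    assert (rep["accuracy"] == 0.0).all()


def test_missing_prediction_is_an_error():
    obs = pd.Series({"P1": "H1", "P2": "H1"})
    preds = _preds({"P1": ["H1"]})
    with pytest.raises(ValueError, match="P2"):
        topk_accuracy(preds, obs, ks=(1,))


def test_accuracy_matches_membership_brute_force(rng):
    hosps = [f"H{j}" for j in range(6)]
    rankings = {f"P{i}": list(rng.permutation(hosps)) for i in range(50)}
    obs = pd.Series({p: rng.choice(hosps) for p in rankings})
    preds = _preds(rankings)
    strata = pd.Series({p: ("AA" if i < 25 else "BB") for i, p in enumerate(rankings)})
    rep = topk_accuracy(preds, obs, ks=(1, 2, 3), strata=strata)
    for _, row in rep.iterrows():
        ids = obs.index if row["stratum"] == "overall" else strata.index[strata == row["stratum"]]
        want = sum(obs[p] in rankings[p][: int(row["k"])] for p in ids)
        assert row["n_correct"] == want and row["n_total"] == len(ids)
    # monotone in k within stratum
    for stratum, grp in rep.groupby("stratum"):
        accs = grp.sort_values("k")["accuracy"].to_numpy()
        assert np.all(np.diff(accs) >= 0)


def test_stratum_counts_sum_to_overall(rng):
    hosps = [f"H{j}" for j in range(4)]
    rankings = {f"P{i}": list(rng.permutation(hosps)) for i in range(40)}
    obs = pd.Series({p: rng.choice(hosps) for p in rankings})
    strata = pd.Series({p: rng.choice(["AA", "BB"]) for p in rankings})
    rep = topk_accuracy(_preds(rankings), obs, ks=(1,), strata=strata)
    overall = rep.loc[rep["stratum"] == "overall", "n_correct"].iloc[0]
    states = rep.loc[rep["stratum"] != "overall", "n_correct"].sum()
    assert overall == states


def test_sufficiency_truth_table_matches_oracle():
    combos = list(itertools.product([False, True], repeat=3))
    idx = [f"P{i}" for i in range(8)]
    m1 = pd.Series([c[0] for c in combos], index=idx)
    m2 = pd.Series([c[1] for c in combos], index=idx)
    m3 = pd.Series([c[2] for c in combos], index=idx)
    out = classify_sufficiency(m1, m2, m3)

    def oracle(a, b, c):
        if a and b and c:
            return "all_correct"
        if not a and (b or c):
            return "model2or3_only"
        if a:
            return "model1_not_all"
        return "none_correct"

    for p, (a, b, c) in zip(idx, combos):
        assert out.loc[p, "class"] == oracle(a, b, c)
        assert out.loc[p, "model1_sufficient"] == a
    # (T,T,T) counted in the model-1 margin and in all_correct
    assert out.loc["P7", "class"] == "all_correct" and out.loc["P7", "model1_sufficient"]


def test_sufficiency_classes_partition_cohort(rng):
    n = 500
    idx = [f"P{i}" for i in range(n)]
    ms = [pd.Series(rng.random(n) < 0.4, index=idx) for _ in range(3)]
    out = classify_sufficiency(*ms)
    counts = out["class"].value_counts()
    assert counts.sum() == n
    assert set(counts.index) <= set(SUFFICIENCY_CLASSES)
    tab = sufficiency_counts(out)
    class_rows = tab.loc[tab["group"].isin(SUFFICIENCY_CLASSES)]
    assert class_rows.loc[class_rows["stratum"] == "overall", "n"].sum() == n


def _dm():
    zips = ["00001", "00002"]
    hosps = ["H1", "H2", "H3"]
    vals = np.array([[1.0, 11.0, 5.0], [7.0, 2.0, 30.0]])
    return DistanceMatrix(zips, hosps, vals, 0.0, 0)


def test_perfect_prediction_has_zero_travel_bias():
    dm = _dm()
    obs = pd.Series({"P1": "H1", "P2": "H2"})
    home = pd.Series({"P1": "00001", "P2": "00002"})
    tb = travel_bias(obs, obs, home, dm)
    row = tb.loc[tb["stratum"] == "overall"].iloc[0]
    assert row["mean_bias"] == 0.0 and row["sd_bias"] == 0.0


def test_two_patient_bias_matches_closed_form():
    dm = _dm()
    home = pd.Series({"P1": "00001", "P2": "00002"})
    obs = pd.Series({"P1": "H2", "P2": "H1"})   # distances 11, 7
    pred = pd.Series({"P1": "H1", "P2": "H3"})  # distances 1, 30 -> diffs +10, -23
    tb = travel_bias(pred, obs, home, dm)
    diffs = np.array([10.0, -23.0])
    row = tb.loc[tb["stratum"] == "overall"].iloc[0]
    assert row["mean_bias"] == pytest.approx(diffs.mean())
    assert row["sd_bias"] == pytest.approx(diffs.std(ddof=1))


def test_travel_bias_matches_direct_recomputation(rng):
    n = 100
    zips = [f"{i + 1:05d}" for i in range(10)]
    hosps = [f"H{j}" for j in range(5)]
    vals = rng.uniform(1, 50, size=(10, 5))
    dm = DistanceMatrix(zips, hosps, vals, 0.0, 0)
    idx = [f"P{i}" for i in range(n)]
    home = pd.Series(rng.choice(zips, n), index=idx)
    obs = pd.Series(rng.choice(hosps, n), index=idx)
    pred = pd.Series(rng.choice(hosps, n), index=idx)
    tb = travel_bias(pred, obs, home, dm).set_index("stratum")
    diffs = np.array(
        [dm.lookup(home[p], obs[p]) - dm.lookup(home[p], pred[p]) for p in idx]
    )
    assert tb.loc["overall", "mean_bias"] == pytest.approx(diffs.mean())
    assert tb.loc["overall", "sd_bias"] == pytest.approx(diffs.std(ddof=1))


def _patients_frame(n, rng, shift=0.0, group=None):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "age": rng.normal(65 + shift, 10, n),
            "sex": rng.choice(["male", "female"], n),
            "payer": rng.choice(["medicare", "private"], n),
            "sdi": rng.normal(50, 20, n),
            "died_in_hospital": rng.random(n) < 0.05,
        }
    )


def test_identical_groups_yield_null_comparisons(rng):
    half = _patients_frame(60, rng)
    pats = pd.concat(
        [half, half.assign(patient_id=[f"Q{i}" for i in range(60)])], ignore_index=True
    )
    grouping = pd.Series(
        ["a"] * 60 + ["b"] * 60, index=list(half["patient_id"]) + [f"Q{i}" for i in range(60)]
    )
    out = subgroup_table(pats, grouping, ["age", "sex", "payer"])
    assert (out["p_value"] > 0.999).all()


def test_chi_square_matches_closed_form():
    pats = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(60)],
            "sex": ["male"] * 20 + ["female"] * 10 + ["male"] * 10 + ["female"] * 20,
        }
    )
    grouping = pd.Series(["a"] * 30 + ["b"] * 30, index=pats["patient_id"])
    out = subgroup_table(pats, grouping, ["sex"])
    # Pearson chi2 for table (20,10 / 10,20): n(ad-bc)^2 / (row/col margins)
    chi2 = 60 * (20 * 20 - 10 * 10) ** 2 / (30 * 30 * 30 * 30)
    want_p = stats.chi2.sf(chi2, df=1)
    assert out["p_value"].iloc[0] == pytest.approx(want_p, rel=1e-10)


def test_separated_continuous_variable_is_significant(rng):
    a = _patients_frame(50, rng)
    b = _patients_frame(50, rng, shift=100.0)  # 10 SDs apart
    b["patient_id"] = [f"Q{i}" for i in range(50)]
    pats = pd.concat([a, b], ignore_index=True)
    grouping = pd.Series(["a"] * 50 + ["b"] * 50, index=pats["patient_id"])
    out = subgroup_table(pats, grouping, ["age"])
    assert out["p_value"].iloc[0] < 1e-6


def test_empty_group_is_an_error(rng):
    pats = _patients_frame(10, rng)
    grouping = pd.Series(["a"] * 10, index=pats["patient_id"])
    with pytest.raises(ValueError):
        subgroup_table(pats, grouping, ["age"])


def test_correctness_requires_full_coverage(small_bundle):
    preds = small_bundle.predictions["overall"][1]
    obs = small_bundle.patients.set_index("patient_id")["hospital_id"]
    hit1 = correctness(preds, obs, 1)
    hit3 = correctness(preds, obs, 3)
    assert hit1.index.equals(obs.index)
    assert (hit3 | ~hit1).all()  # top-1 hits are top-3 hits
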