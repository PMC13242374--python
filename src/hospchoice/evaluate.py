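"""Evaluation: top-k accuracy, model-sufficiency classes, travel-distance bias,
and descriptive subgroup comparison tables.

Accuracy is the fraction of patients whose observed hospital is among the k
highest-scoring predicted hospitals.  Per-patient correctness under the three
model specifications is summarised into sufficiency classes (which models, if
any, predicted the observed hospital).  Travel bias is the signed difference
(observed distance - distance to the top predicted hospital): positive means
the model underestimates real travel.  Subgroup tables compare patient
characteristics across classification groups with Welch t-tests for
continuous variables and Pearson chi-square (no continuity correction) for
categoricals.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo import DistanceMatrix

#: Exclusive, exhaustive per-patient sufficiency classes at a fixed k.
SUFFICIENCY_CLASSES = ["all_correct", "model2or3_only", "model1_not_all", "none_correct"]


def correctness(predictions: pd.DataFrame, observed: pd.Series, k: int) -> pd.Series:
    """Per-patient indicator that the observed hospital is in the top k.

    ``predictions`` is the long frame from :func:`hospchoice.predict.predict_topk`
    (ranks 1..k or more).  Every patient in ``observed`` must have at least
    one predicted rank; missing patients raise instead of being dropped.
    """
    topk = predictions.loc[predictions["rank"] <= k]
    missing = observed.index.difference(topk["patient_id"].unique())
    if len(missing) > 0:
        raise ValueError(f"patients without predictions: {list(missing[:10])}")
    hit = (
        topk.assign(observed=topk["patient_id"].map(observed))
        .assign(hit=lambda f: f["hospital_id"] == f["observed"])
        .groupby("patient_id")["hit"]
        .any()
    )
    return hit.reindex(observed.index).astype(bool)


def _iter_strata(observed_index: pd.Index, strata):
    yield "overall", observed_index
    if strata is None:
        return
    if isinstance(strata, pd.Series):
        for label, idx in strata.groupby(strata).groups.items():
            yield str(label), observed_index.intersection(idx)
    else:
        for label, ids in strata.items():
            yield str(label), observed_index.intersection(pd.Index(ids))


def topk_accuracy(
    predictions: pd.DataFrame,
    observed: pd.Series,
    ks: Sequence[int] = (1, 2, 3),
    strata: pd.Series | Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Accuracy per (stratum, k) for one fitted model.

    ``observed`` maps patient_id -> observed hospital; ``strata`` is either a
    Series mapping patient_id -> stratum label or a mapping of label ->
    patient ids.  The ``overall`` stratum is always reported.
    """
    rows = []
    hits = {k: correctness(predictions, observed, k) for k in ks}
    for label, idx in _iter_strata(observed.index, strata):
        for k in ks:
            h = hits[k].loc[idx]
            rows.append(
                {"stratum": label, "k": k, "n_correct": int(h.sum()),
                 "n_total": len(h), "accuracy": float(h.mean()) if len(h) else np.nan}
            )
    return pd.DataFrame(rows)


def classify_sufficiency(
    correct_m1: pd.Series, correct_m2: pd.Series, correct_m3: pd.Series
) -> pd.DataFrame:
    """Per-patient sufficiency classification at a fixed k.

    Returns one row per patient with the exclusive class plus the marginal
    indicators.  Exclusive classes partition the cohort:

    - ``all_correct``: every model predicted the observed hospital;
    - ``model2or3_only``: model 2 or 3 correct, model 1 wrong;
    - ``model1_not_all``: model 1 correct but not all three;
    - ``none_correct``: every model wrong.

    ``model1_sufficient`` (the margin: model 1 correct, regardless of the
    others) is reported alongside because published sufficiency tables use
    the margin, which overlaps ``all_correct``.
    """
    m1, m2, m3 = (s.astype(bool) for s in (correct_m1, correct_m2, correct_m3))
    cls = pd.Series("none_correct", index=m1.index, dtype=object)
    cls[m1 & m2 & m3] = "all_correct"
    cls[~m1 & (m2 | m3)] = "model2or3_only"
    cls[m1 & ~(m2 & m3)] = "model1_not_all"
    return pd.DataFrame(
        {
            "class": pd.Categorical(cls, categories=SUFFICIENCY_CLASSES),
            "model1_sufficient": m1,
            "model2_sufficient": m2,
            "model3_sufficient": m3,
        }
    )


def travel_bias(
    top1_hospital: pd.Series,
    observed_hospital: pd.Series,
    home_zip: pd.Series,
    distances: DistanceMatrix,
    strata: pd.Series | Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Mean +/- SD of (observed - predicted) travel distance in miles.

    All three inputs are indexed by patient_id.  A positive mean says the
    model under-predicts how far patients actually travel.
    """
    d_obs = np.array(
        [distances.lookup(z, h) for z, h in zip(home_zip, observed_hospital.loc[home_zip.index])]
    )
    d_pred = np.array(
        [distances.lookup(z, h) for z, h in zip(home_zip, top1_hospital.loc[home_zip.index])]
    )
    diff = pd.Series(d_obs - d_pred, index=home_zip.index)
    rows = []
    for label, idx in _iter_strata(diff.index, strata):
        x = diff.loc[idx]
        rows.append(
            {"stratum": label, "n": len(x), "mean_bias": float(x.mean()),
             "sd_bias": float(x.std(ddof=1)) if len(x) > 1 else 0.0}
        )
    return pd.DataFrame(rows)


def subgroup_table(
    patients: pd.DataFrame,
    grouping: pd.Series,
    variables: Sequence[str],
) -> pd.DataFrame:
    """Descriptive two-group comparison of patient characteristics.

    ``grouping`` maps patient_id -> group label; patients with a null label
    are excluded from the comparison.  Continuous variables are summarised
    as mean +/- SD with a Welch two-sample t-test; categorical and boolean
    variables as n (%) per level with a Pearson chi-square test (no
    continuity correction).  Expected cell counts below 1 attach a warning
    to the affected rows.
    """
    grouping = grouping.dropna()
    groups = sorted(grouping.unique())
    if len(groups) != 2:
        raise ValueError(f"subgroup comparison requires exactly 2 groups, got {groups}")
    sub = patients.loc[patients["patient_id"].isin(grouping.index)].set_index("patient_id")
    labels = grouping.loc[sub.index]
    for g in groups:
        if (labels == g).sum() == 0:
            raise ValueError(f"group {g!r} is empty")

    rows = []
    for var in variables:
        col = sub[var]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col) \
                and col.nunique() > 2:
            a = col[labels == groups[0]].to_numpy(dtype=float)
            b = col[labels == groups[1]].to_numpy(dtype=float)
            if np.isclose(a.var(ddof=1) + b.var(ddof=1), 0.0) and np.isclose(a.mean(), b.mean()):
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            rows.append(
                {"variable": var, "level": "",
                 groups[0]: f"{a.mean():.1f} ± {a.std(ddof=1):.1f}",
                 groups[1]: f"{b.mean():.1f} ± {b.std(ddof=1):.1f}",
                 "p_value": p, "warning": ""}
            )
        else:
            table = pd.crosstab(col, labels).reindex(columns=groups, fill_value=0)
            if table.shape[0] < 2:
                chi2_p, warn = 1.0, "single level observed"
                expected_min = np.inf
            else:
                chi2, chi2_p, _, expected = stats.chi2_contingency(
                    table.to_numpy(), correction=False
                )
                expected_min = expected.min()
                warn = "expected cell count < 1" if expected_min < 1 else ""
            n0, n1 = (labels == groups[0]).sum(), (labels == groups[1]).sum()
            for level in table.index:
                c0, c1 = table.loc[level, groups[0]], table.loc[level, groups[1]]
                rows.append(
                    {"variable": var, "level": str(level),
                     groups[0]: f"{c0} ({100 * c0 / n0:.1f})",
                     groups[1]: f"{c1} ({100 * c1 / n1:.1f})",
                     "p_value": float(chi2_p), "warning": warn}
                )
    return pd.DataFrame(rows)


def sufficiency_counts(classes: pd.DataFrame, strata=None) -> pd.DataFrame:
    """Counts and fractions of sufficiency classes plus the model margins."""
    rows = []
    for label, idx in _iter_strata(classes.index, strata):
        sub = classes.loc[idx]
        n = len(sub)
        for c in SUFFICIENCY_CLASSES:
            cnt = int((sub["class"] == c).sum())
            rows.append({"stratum": label, "group": c, "n": cnt, "fraction": cnt / n if n else np.nan})
        for m in ("model1_sufficient", "model2_sufficient", "model3_sufficient"):
            cnt = int(sub[m].sum())
            rows.append({"stratum": label, "group": m, "n": cnt, "fraction": cnt / n if n else np.nan})
    return pd.DataFrame(rows)
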