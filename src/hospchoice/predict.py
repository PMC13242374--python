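"""Scoring, ranking, and top-k hospital prediction under a fitted gravity model.

Every patient is scored against every candidate hospital (all in-state
hospitals observed in the cohort).  The linear predictor uses only the
fitted model's named regressors — log distance (spec 1), plus log volume
(spec 2), plus the four hospital characteristics (spec 3).  Scores are
converted to choice probabilities by a softmax over the candidate set; the
predicted hospital is the highest-probability one, with exact score ties
broken by a seeded random permutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import HOSPITAL_COVARIATES
from .geo import DistanceMatrix
from .gravity import GravityFit

logger = logging.getLogger(__name__)

#: Default tie-break seed, recorded with every prediction run.
DEFAULT_SEED = 20160101


@dataclass
class PredictionResult:
    """Full ranking for one patient."""

    patient_id: str
    ranked_hospitals: list
    scores: np.ndarray          # aligned with ranked_hospitals
    probabilities: np.ndarray   # aligned with ranked_hospitals
    tie_groups: list            # lists of hospital ids with exactly equal scores
    seed: int


def score_pairs(
    fit: GravityFit,
    patient_zip: str,
    hospitals: pd.DataFrame,
    distances: DistanceMatrix,
    use_residual_effects: bool = False,
) -> pd.Series:
    """Linear predictor for one origin ZIP against a candidate hospital table.

    Origin fixed effects are constant within a patient and omitted (they
    cannot change the ranking).  With ``use_residual_effects`` the stage-2
    residual of the destination effect is added for hospitals present in the
    fit; absent hospitals are scored without it and logged.
    """
    ids = hospitals.index
    d = np.array([distances.lookup(patient_zip, h) for h in ids])
    scores = fit.beta_distance * np.log(d)
    if fit.model_spec >= 2:
        scores = scores + fit.beta_log_volume * np.log(
            hospitals["volume"].to_numpy(dtype=float)
        )
    if fit.model_spec == 3:
        x = hospitals[HOSPITAL_COVARIATES].to_numpy(dtype=float)
        scores = scores + x @ fit.gamma.to_numpy()
    if use_residual_effects and fit.stage2_residuals is not None:
        resid = fit.stage2_residuals.reindex(ids)
        absent = resid.index[resid.isna()].tolist()
        if absent:
            logger.warning(
                "hospitals absent from fitted destination set scored without "
                "residual effect: %s", absent
            )
        scores = scores + resid.fillna(0.0).to_numpy()
    return pd.Series(scores, index=ids, name="score")


def softmax_probabilities(scores) -> np.ndarray:
    """Numerically stable softmax; order-preserving, sums to one."""
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("cannot compute choice probabilities for an empty score set")
    if np.any(~np.isfinite(s)):
        raise ValueError("scores must be finite")
    e = np.exp(s - s.max())
    return e / e.sum()


def rank_hospitals(scores: pd.Series, seed: int = DEFAULT_SEED, rng=None):
    """Rank hospitals by descending score with seeded random tie-breaking.

    Returns ``(ranked_ids, tie_groups)``.  Distinct scores rank by pure
    argsort; hospitals with exactly equal scores are ordered by a random
    permutation drawn from ``rng`` (or ``default_rng(seed)``), so the result
    is deterministic given ``(scores, seed)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    s = scores.to_numpy(dtype=float)
    if np.any(~np.isfinite(s)):
        raise ValueError("scores must be finite")
    n = len(s)
    # find exact-equality tie groups before consuming randomness
    tie_groups = []
    has_ties = False
    _, inverse, counts = np.unique(s, return_inverse=True, return_counts=True)
    if np.any(counts > 1):
        has_ties = True
        for g in np.flatnonzero(counts > 1):
            tie_groups.append([scores.index[i] for i in np.flatnonzero(inverse == g)])
    if has_ties:
        tiebreak = rng.permutation(n)
    else:
        tiebreak = np.arange(n)
    order = np.lexsort((tiebreak, -s))
    ranked = [scores.index[i] for i in order]
    return ranked, tie_groups


def predict_patient(
    fit: GravityFit,
    patient_id: str,
    patient_zip: str,
    hospitals: pd.DataFrame,
    distances: DistanceMatrix,
    seed: int = DEFAULT_SEED,
    rng=None,
    use_residual_effects: bool = False,
) -> PredictionResult:
    """Full scored ranking for a single patient."""
    scores = score_pairs(fit, patient_zip, hospitals, distances, use_residual_effects)
    probs = softmax_probabilities(scores.to_numpy())
    ranked, ties = rank_hospitals(scores, seed=seed, rng=rng)
    pos = {h: i for i, h in enumerate(scores.index)}
    order = [pos[h] for h in ranked]
    return PredictionResult(
        patient_id=patient_id,
        ranked_hospitals=ranked,
        scores=scores.to_numpy()[order],
        probabilities=probs[order],
        tie_groups=ties,
        seed=seed,
    )


def predict_topk(
    fit: GravityFit,
    patients: pd.DataFrame,
    hospitals: pd.DataFrame,
    distances: DistanceMatrix,
    centroids: pd.DataFrame,
    k: int = 1,
    seed: int = DEFAULT_SEED,
    use_residual_effects: bool = False,
) -> pd.DataFrame:
    """Top-k predicted hospitals for every patient.

    The candidate set is the in-state hospitals (hospital state == state of
    the patient's home-ZIP centroid).  Tie-breaking consumes an independent
    seeded stream per patient (keyed by seed and patient position), so
    predictions for one patient never depend on k or on other patients.

    Returns a long DataFrame ``patient_id, rank, hospital_id, score,
    probability`` with ranks 1..k (truncated, with a warning, if k exceeds
    the candidate count).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    hospitals = hospitals.set_index("hospital_id") if "hospital_id" in hospitals.columns else hospitals

    home_state = patients["home_zip"].map(centroids["state"])
    candidates_by_state = {
        s: hospitals.loc[hospitals["state"] == s] for s in home_state.unique()
    }
    for s, cand in candidates_by_state.items():
        if len(cand) == 0:
            raise ValueError(f"no candidate hospitals in state {s!r}")
        if k > len(cand):
            warnings.warn(
                f"k={k} exceeds the {len(cand)} candidate hospitals in state {s!r}; "
                "rankings are truncated"
            )

    # scores, probabilities and (absent ties) the ranking depend only on the
    # home ZIP: compute once per ZIP; consume per-patient randomness only
    # where exact ties exist so predictions are independent across patients
    zip_cache: dict[str, tuple] = {}
    for z in patients["home_zip"].unique():
        cand = candidates_by_state[centroids.loc[z, "state"]]
        s = score_pairs(fit, z, cand, distances, use_residual_effects)
        probs = softmax_probabilities(s.to_numpy())
        ranked, ties = rank_hospitals(s, seed=seed)
        pos = {h: i for i, h in enumerate(s.index)}
        fixed_rows = None
        if not ties:
            fixed_rows = [
                (r, h, float(s.iloc[pos[h]]), float(probs[pos[h]]))
                for r, h in enumerate(ranked[:k], start=1)
            ]
        zip_cache[z] = (s, probs, pos, fixed_rows)

    rows = []
    for ordinal, (pid, z) in enumerate(zip(patients["patient_id"], patients["home_zip"])):
        scores, probs, pos, fixed_rows = zip_cache[z]
        if fixed_rows is not None:
            rows.extend((pid, *row) for row in fixed_rows)
            continue
        rng = np.random.default_rng([seed, ordinal])
        ranked, _ = rank_hospitals(scores, rng=rng)
        for r, h in enumerate(ranked[:k], start=1):
            rows.append((pid, r, h, float(scores.iloc[pos[h]]), float(probs[pos[h]])))
    out = pd.DataFrame(rows, columns=["patient_id", "rank", "hospital_id", "score", "probability"])
    out.attrs["seed"] = seed
    return out
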