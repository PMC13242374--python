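"""Gravity-model estimation by two-way double-demeaning.

The flow model is log T_ij = alpha_i + delta_j + beta_d * log d_ij + e_ij,
with origin (ZIP) and destination (hospital) fixed effects.  Estimation is
two-stage:

Stage 1
    The pair-varying regressor (log distance) and the outcome are double-
    demeaned — origin-group and destination-group means are subtracted
    alternately until all group means vanish (one pass suffices on balanced
    grids; unbalanced panels iterate).  The slope of the demeaned outcome on
    the demeaned regressor is the distance elasticity ``beta_distance``,
    identical to explicit two-way dummy-variable least squares.  Pairs are
    weighted by their flow count T_ij: the log of a Poisson-like count has
    variance ~ 1/E[T], so count weights are the variance-stabilising choice
    and prevent the many small distant cells from attenuating the distance
    elasticity.

Stage 2
    Destination fixed effects delta_j are recovered from the stage-1
    residual surface by alternating projections and, for specifications
    that include hospital covariates, regressed on log volume (model 2) or
    on log volume plus four binary hospital characteristics (model 3) by
    weighted least squares, weights = number of positive-flow origins per
    destination.  Destination demeaning annihilates destination-invariant
    regressors, so their coefficients can only be identified this way.

Model specifications: 1 = distance only; 2 = distance + log volume;
3 = distance + log volume + (medical-school affiliation, rurality, cancer
accreditation, centralized health system).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .cohort import HOSPITAL_COVARIATES
from .flows import FlowTable
from .geo import DistanceMatrix

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 100_000


class ConvergenceError(RuntimeError):
    """Double-demeaning failed to converge within the iteration budget."""


class DegenerateRegressorError(ValueError):
    """A regressor is constant (or collinear) within the estimation sample."""


def _group_means(
    values: np.ndarray, idx: np.ndarray, n_groups: int, weights: np.ndarray | None
) -> np.ndarray:
    if weights is None:
        sums = np.bincount(idx, weights=values, minlength=n_groups)
        counts = np.bincount(idx, minlength=n_groups)
    else:
        sums = np.bincount(idx, weights=weights * values, minlength=n_groups)
        counts = np.bincount(idx, weights=weights, minlength=n_groups)
    return sums / counts


def double_demean(
    values,
    origin_ids: Sequence,
    destination_ids: Sequence,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    weights=None,
):
    """Remove origin and destination group means by alternating projections.

    Parameters
    ----------
    values : array-like, one observation per (origin, destination) pair.
    origin_ids, destination_ids : group labels per observation.
    tol : convergence threshold on the largest absolute group-mean
        adjustment in a sweep.
    max_iter : sweep budget; exceeded -> :class:`ConvergenceError`.
    weights : optional positive observation weights; group means become
        weighted means, making the transform the within-projection of
        weighted two-way least squares.  ``None`` (default) is the plain
        unweighted transform.

    Returns
    -------
    demeaned : ndarray
    origin_means : pd.Series  — accumulated per-origin contributions
    destination_means : pd.Series — accumulated per-destination contributions
    n_iter : int
    """
    v = np.asarray(values, dtype=float).copy()
    ocodes, olabels = pd.factorize(np.asarray(origin_ids))
    dcodes, dlabels = pd.factorize(np.asarray(destination_ids))
    if len(olabels) < 2 or len(dlabels) < 2:
        raise ValueError(
            f"double demeaning needs >=2 origins and >=2 destinations, "
            f"got {len(olabels)} x {len(dlabels)}"
        )
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0):
            raise ValueError("weights must be strictly positive")
    acc_o = np.zeros(len(olabels))
    acc_d = np.zeros(len(dlabels))
    for it in range(1, max_iter + 1):
        om = _group_means(v, ocodes, len(olabels), weights)
        v -= om[ocodes]
        acc_o += om
        dm = _group_means(v, dcodes, len(dlabels), weights)
        v -= dm[dcodes]
        acc_d += dm
        if max(np.max(np.abs(om)), np.max(np.abs(dm))) < tol:
            return (
                v,
                pd.Series(acc_o, index=olabels),
                pd.Series(acc_d, index=dlabels),
                it,
            )
    raise ConvergenceError(
        f"double demeaning did not converge in {max_iter} sweeps "
        f"(last max |group mean| = {max(np.max(np.abs(om)), np.max(np.abs(dm))):.3e}); "
        f"panel {len(olabels)} x {len(dlabels)}, n={len(v)}"
    )


@dataclass
class GravityFit:
    """Estimated gravity-model coefficients and fixed effects for one spec."""

    model_spec: int
    beta_distance: float
    beta_log_volume: float | None
    gamma: pd.Series | None              # 4 covariate coefficients (spec 3)
    origin_effects: pd.Series            # alpha_i per origin ZIP
    destination_effects: pd.Series       # delta_j per hospital
    stage2_residuals: pd.Series | None   # delta_j net of stage-2 fit (specs 2-3)
    stage2_stderr: pd.Series | None
    volumes: pd.Series                   # log-volume source used in scoring
    hospital_covariates: pd.DataFrame | None
    n_obs: int
    residual_sd: float
    demeaning_iterations: int
    converged: bool = True
    stratum: str = "overall"

    def coefficients(self) -> pd.Series:
        out = {"beta_distance": self.beta_distance}
        if self.beta_log_volume is not None:
            out["beta_log_volume"] = self.beta_log_volume
        if self.gamma is not None:
            out.update({f"gamma_{k}": v for k, v in self.gamma.items()})
        return pd.Series(out)


class GravityChoiceModel(BaseEstimator):
    """Two-way fixed-effects gravity model of origin-destination patient flows.

    Parameters
    ----------
    model_spec : {1, 2, 3}
        1 = log distance only; 2 = + log hospital volume; 3 = + four binary
        hospital characteristics.
    demean_tol, demean_max_iter : convergence control for the alternating
        within-transformation.

    Attributes (after :meth:`fit`)
    ------------------------------
    beta_distance_ : float — elasticity of flows w.r.t. distance.
    beta_log_volume_ : float or None — elasticity w.r.t. hospital volume.
    gamma_ : pd.Series or None — hospital-characteristic coefficients.
    origin_effects_, destination_effects_ : recovered fixed effects.
    result_ : :class:`GravityFit` — the full fit record.
    """

    def __init__(
        self,
        model_spec: int = 2,
        demean_tol: float = DEFAULT_TOL,
        demean_max_iter: int = DEFAULT_MAX_ITER,
    ):
        self.model_spec = model_spec
        self.demean_tol = demean_tol
        self.demean_max_iter = demean_max_iter

    # -- estimation ------------------------------------------------------

    def fit(
        self,
        flow_table: FlowTable,
        distances: DistanceMatrix,
        hospitals: pd.DataFrame | None = None,
        stratum: str = "overall",
    ) -> "GravityChoiceModel":
        """Estimate the gravity model on positive flows.

        ``hospitals`` (indexed by hospital_id, with a ``volume`` column and
        the four binary characteristic columns) is required for specs 2-3.
        """
        if self.model_spec not in (1, 2, 3):
            raise ValueError(f"model_spec must be 1, 2 or 3, got {self.model_spec!r}")
        if self.model_spec >= 2 and hospitals is None:
            raise ValueError("hospitals table required for model specs 2 and 3")

        entries = flow_table.entries
        y = np.log(entries["count"].to_numpy(dtype=float))
        d = np.array(
            [distances.lookup(o, h) for o, h in zip(entries["origin_zip"], entries["hospital_id"])]
        )
        x = np.log(d)
        origins = entries["origin_zip"].to_numpy()
        dests = entries["hospital_id"].to_numpy()

        # count weights: Var[log T] ~ 1/E[T] for Poisson-like counts, so
        # weighting each pair by T_ij is the variance-stabilising choice and
        # avoids the small-count attenuation of the distance elasticity
        w = entries["count"].to_numpy(dtype=float)

        xd, _, _, it_x = double_demean(
            x, origins, dests, self.demean_tol, self.demean_max_iter, weights=w
        )
        yd, _, _, it_y = double_demean(
            y, origins, dests, self.demean_tol, self.demean_max_iter, weights=w
        )
        sxx = float((w * xd) @ xd)
        if sxx < 1e-12 * float(w.sum()):
            raise DegenerateRegressorError(
                "log distance is constant within the two-way demeaned sample"
            )
        beta_distance = float((w * xd) @ yd) / sxx

        # recover fixed effects from the residual surface
        r = y - beta_distance * x
        _, alpha, delta, _ = double_demean(
            r, origins, dests, self.demean_tol, self.demean_max_iter, weights=w
        )
        # identification: destination effects mean-zero, constant in origins
        shift = float(delta.mean())
        delta = delta - shift
        alpha = alpha + shift
        resid = r - alpha.loc[origins].to_numpy() - delta.loc[dests].to_numpy()
        residual_sd = (
            float(np.sqrt(np.average(resid**2, weights=w))) if len(resid) > 1 else 0.0
        )

        beta_log_volume = None
        gamma = None
        stage2_resid = None
        stage2_se = None
        covs = None
        volumes = None
        if self.model_spec >= 2:
            volumes = hospitals.loc[delta.index, "volume"].astype(float)
            design = pd.DataFrame({"log_volume": np.log(volumes)}, index=delta.index)
            if self.model_spec == 3:
                covs = hospitals.loc[delta.index, HOSPITAL_COVARIATES].astype(float)
                design = pd.concat([design, covs], axis=1)
            degenerate = [c for c in design.columns if design[c].nunique() <= 1]
            if degenerate:
                raise DegenerateRegressorError(
                    f"destination covariates constant across hospitals: {degenerate}"
                )
            X = sm.add_constant(design, has_constant="add")
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                raise DegenerateRegressorError(
                    f"collinear destination covariates among: {list(design.columns)}"
                )
            if len(delta) <= X.shape[1]:
                raise ValueError(
                    f"stage 2 needs more destinations ({len(delta)}) than regressors ({X.shape[1]})"
                )
            weights = (
                entries.groupby("hospital_id")["origin_zip"].nunique().loc[delta.index].to_numpy()
            )
            wls = sm.WLS(delta.to_numpy(), X, weights=weights).fit()
            params = pd.Series(wls.params, index=X.columns)
            beta_log_volume = float(params["log_volume"])
            if self.model_spec == 3:
                gamma = params[HOSPITAL_COVARIATES]
            stage2_resid = pd.Series(wls.resid, index=delta.index)
            stage2_se = pd.Series(wls.bse, index=X.columns)

        self.result_ = GravityFit(
            model_spec=self.model_spec,
            beta_distance=beta_distance,
            beta_log_volume=beta_log_volume,
            gamma=gamma,
            origin_effects=alpha,
            destination_effects=delta,
            stage2_residuals=stage2_resid,
            stage2_stderr=stage2_se,
            volumes=volumes if volumes is not None else pd.Series(dtype=float),
            hospital_covariates=covs,
            n_obs=len(entries),
            residual_sd=residual_sd,
            demeaning_iterations=max(it_x, it_y),
            converged=True,
            stratum=stratum,
        )
        self.beta_distance_ = beta_distance
        self.beta_log_volume_ = beta_log_volume
        self.gamma_ = gamma
        self.origin_effects_ = alpha
        self.destination_effects_ = delta
        self.n_obs_ = len(entries)
        return self

    # -- prediction (delegates to the predict module) --------------------

    def predict_topk(self, patients, hospitals, distances, centroids, k=1, **kwargs):
        """Top-k predicted hospitals per patient; see :func:`hospchoice.predict.predict_topk`."""
        from .predict import predict_topk

        self._check_fitted()
        return predict_topk(self.result_, patients, hospitals, distances, centroids, k=k, **kwargs)

    def _check_fitted(self) -> None:
        if not hasattr(self, "result_"):
            raise RuntimeError("GravityChoiceModel is not fitted; call fit() first")


def fit_gravity(
    flow_table: FlowTable,
    distances: DistanceMatrix,
    hospitals: pd.DataFrame | None = None,
    model_spec: int = 2,
    stratum: str = "overall",
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> GravityFit:
    """Functional wrapper over :class:`GravityChoiceModel`."""
    est = GravityChoiceModel(model_spec=model_spec, demean_tol=tol, demean_max_iter=max_iter)
    est.fit(flow_table, distances, hospitals, stratum=stratum)
    return est.result_


def fit_all(
    flow_table: FlowTable,
    distances: DistanceMatrix,
    hospitals: pd.DataFrame,
    centroids: pd.DataFrame,
    specs: Sequence[int] = (1, 2, 3),
    strata: Mapping[str, Sequence[str]] | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    on_error: str = "raise",
) -> dict[str, dict[int, GravityFit]]:
    """Fit every spec for the pooled cohort and separately per state.

    ``strata`` maps stratum name -> list of states whose origin ZIPs belong
    to it; by default one stratum per state in the flow table plus
    ``"overall"`` covering everything.  With ``on_error="skip"`` a
    (stratum, spec) whose fit is degenerate — e.g. too few destinations in a
    small state to identify spec-3 covariates — is dropped with a logged
    warning instead of aborting the whole set.
    """
    if on_error not in ("raise", "skip"):
        raise ValueError(f"on_error must be 'raise' or 'skip', got {on_error!r}")
    origin_state = flow_table.entries["origin_zip"].map(centroids["state"])
    if strata is None:
        strata = {s: [s] for s in sorted(origin_state.dropna().unique())}
    fits: dict[str, dict[int, GravityFit]] = {}
    for name, states in [("overall", None)] + sorted(strata.items()):
        if states is None:
            sub = flow_table
        else:
            mask = origin_state.isin(states)
            if not mask.any():
                logger.warning("stratum %s has no flows; skipped", name)
                continue
            sub = FlowTable(flow_table.entries.loc[mask].reset_index(drop=True))
        fits[name] = {}
        for spec in specs:
            try:
                fits[name][spec] = fit_gravity(
                    sub, distances, hospitals, model_spec=spec, stratum=name,
                    tol=tol, max_iter=max_iter,
                )
            except (ValueError, RuntimeError) as exc:
                if on_error == "skip":
                    logger.warning("stratum %r, spec %d skipped: %s", name, spec, exc)
                    continue
                raise type(exc)(f"stratum {name!r}, spec {spec}: {exc}") from exc
    return fits


def fits_to_frame(fits: Mapping[str, Mapping[int, GravityFit]]) -> pd.DataFrame:
    """Flatten a fit dictionary to one row per (stratum, spec, parameter)."""
    rows = []
    for stratum, by_spec in fits.items():
        for spec, fit in by_spec.items():
            for param, est in fit.coefficients().items():
                se = np.nan
                if fit.stage2_stderr is not None:
                    key = param.replace("gamma_", "").replace("beta_log_volume", "log_volume")
                    if key in fit.stage2_stderr.index:
                        se = float(fit.stage2_stderr[key])
                rows.append(
                    {"stratum": stratum, "model_spec": spec, "parameter": param,
                     "estimate": est, "stderr": se, "n_obs": fit.n_obs}
                )
    return pd.DataFrame(rows)
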