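"""Synthetic patient-flow market with known choice parameters.

Real hospital-discharge data of the kind this analysis targets are
restricted, so every module is exercised against a simulated market whose
generating process matches the structure the gravity model assumes:

- ZIP centroids scattered over a rectangular region split into contiguous
  state bands; ZIP populations drawn from a Dirichlet so a few ZIPs dominate;
- hospitals at distinct ZIP centroids with four binary characteristics and a
  latent log-normal attractiveness shifted by those characteristics;
- each patient's hospital drawn from an in-state multinomial logit with
  utility  u_kj = theta_distance*log d_kj + theta_volume*log A_j +
  theta_cov'x_j  (the Gumbel random-utility model);
- demographics, payer, deprivation score and rural-urban status drawn from
  marginals matching a published two-state pancreatectomy cohort; in-hospital
  death probability decreases with the chosen hospital's realized volume.

Choices are driven by *latent* attractiveness A_j while estimation uses the
*realized* cohort volume V_j, deliberately reproducing the volume endogeneity
of cohort-derived volume measures.

All draws are deterministic given the configured seed: each generation stage
consumes an independent stream spawned from it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import HOSPITAL_COVARIATES
from .geo import haversine_miles

GENERATOR_VERSION = "1.0"

# demographic marginals of the emulated two-state surgical cohort
AGE_MEAN, AGE_SD, AGE_MIN = 65.6, 12.3, 19.0
SDI_MEAN, SDI_SD = 50.2, 29.3
P_MALE = 0.529
P_RACE = {"nh_white": 0.655, "black": 0.094, "hispanic": 0.129, "other": 0.122}
P_RURAL_URBAN = {"major_metro": 0.725, "small_metro": 0.234, "micropolitan_rural": 0.041}
P_PAYER = {"medicare": 0.550, "medicaid": 0.102, "private": 0.310, "other": 0.038}
MORTALITY_INTERCEPT = -3.5        # logit scale, at mean log realized volume
MORTALITY_LOG_VOLUME_SLOPE = -0.4


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic market; defaults are the study conditions."""

    seed: int
    n_zips: int = 100
    n_hospitals: int = 15
    n_patients: int = 20_000
    n_states: int = 2
    grid_extent: float = 2.5          # degrees; sized so hospital spatial
                                      # density matches a mid-Atlantic state
                                      # scaled to n_hospitals
    theta_distance: float = -1.5      # true distance coefficient in utility
    theta_volume: float = 1.0         # true attractiveness coefficient
    theta_covariates: tuple = (0.4, -0.3, 0.3, 0.2)
    covariate_prevalences: tuple = (0.6, 0.2, 0.65, 0.45)
    covariate_attractiveness: tuple = (0.5, -0.5, 0.5, 0.3)
    population_concentration: float = 0.5   # Dirichlet alpha over ZIP populations
    attractiveness_dispersion: float = 1.5   # SD of log latent attractiveness;
                                             # matches the heavy volume skew of
                                             # real complex-surgery markets
                                             # (median ~7, IQR 2-26.5)
    floor_miles: float = 0.5
    base_lat: float = 38.0
    base_lon: float = -80.0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_zips", "n_hospitals", "n_patients", "n_states"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_states > self.n_zips:
            raise ValueError("n_states cannot exceed n_zips")
        if self.n_states > self.n_hospitals:
            raise ValueError("every state needs at least one hospital")


def _rng(config: SyntheticConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _state_codes(n: int) -> list[str]:
    return [chr(ord("A") + i // 26) + chr(ord("A") + i % 26) for i in range(n)]


def _split_counts(total: int, parts: int) -> np.ndarray:
    base = np.full(parts, total // parts)
    base[: total % parts] += 1
    return base


def generate_geography(config: SyntheticConfig) -> pd.DataFrame:
    """ZIP centroid table with populations, states as contiguous bands.

    Returns a DataFrame indexed by ``zip`` with ``lat``, ``lon``, ``state``
    and ``population_weight`` columns.
    """
    rng = _rng(config, 0)
    states = _state_codes(config.n_states)
    per_state = _split_counts(config.n_zips, config.n_states)
    band = config.grid_extent / config.n_states
    rows = []
    z = 0
    for s_idx, (state, n_z) in enumerate(zip(states, per_state)):
        lon_lo = config.base_lon + s_idx * band
        for _ in range(n_z):
            rows.append(
                {
                    "zip": f"{z + 1:05d}",
                    "lat": config.base_lat + rng.uniform(0, config.grid_extent),
                    "lon": lon_lo + rng.uniform(0, band),
                    "state": state,
                }
            )
            z += 1
    geo = pd.DataFrame(rows).set_index("zip")
    geo["population_weight"] = rng.dirichlet(
        np.full(config.n_zips, config.population_concentration)
    )
    return geo


def generate_hospitals(config: SyntheticConfig, geography: pd.DataFrame) -> pd.DataFrame:
    """Hospital table with binary characteristics and latent attractiveness.

    Hospitals occupy distinct ZIPs (so no two hospitals are exactly tied in
    distance for every patient) and are spread over states proportionally to
    each state's ZIP count, at least one per state.
    """
    rng = _rng(config, 1)
    states = sorted(geography["state"].unique())
    zip_counts = geography["state"].value_counts()
    raw = zip_counts.loc[states].to_numpy() / len(geography) * config.n_hospitals
    alloc = np.maximum(np.floor(raw).astype(int), 1)
    while alloc.sum() < config.n_hospitals:
        alloc[np.argmax(raw - alloc)] += 1
    while alloc.sum() > config.n_hospitals:
        candidates = np.flatnonzero(alloc > 1)
        alloc[candidates[np.argmin((raw - alloc)[candidates])]] -= 1

    rows = []
    h = 0
    prev = np.asarray(config.covariate_prevalences, dtype=float)
    cov_eff = np.asarray(config.covariate_attractiveness, dtype=float)
    for state, n_h in zip(states, alloc):
        zips = geography.index[geography["state"] == state]
        chosen = rng.choice(zips.to_numpy(), size=n_h, replace=False)
        for zc in chosen:
            x = (rng.random(4) < prev).astype(int)
            log_a = rng.normal(0.0, config.attractiveness_dispersion) + float(cov_eff @ x)
            rows.append(
                {
                    "hospital_id": f"H{h + 1:03d}",
                    "zip": zc,
                    "state": state,
                    **{c: bool(v) for c, v in zip(HOSPITAL_COVARIATES, x)},
                    "latent_attractiveness": float(np.exp(log_a)),
                }
            )
            h += 1
    return pd.DataFrame(rows)


def choice_probabilities(
    config: SyntheticConfig, geography: pd.DataFrame, hospitals: pd.DataFrame
) -> dict[str, pd.Series]:
    """Closed-form multinomial choice probabilities per origin ZIP."""
    theta_cov = np.asarray(config.theta_covariates, dtype=float)
    out: dict[str, pd.Series] = {}
    for zc, zrow in geography.iterrows():
        cand = hospitals.loc[hospitals["state"] == zrow["state"]]
        if len(cand) == 0:
            raise ValueError(f"ZIP {zc} has no in-state hospital candidates")
        d = haversine_miles(
            zrow["lat"], zrow["lon"],
            geography.loc[cand["zip"], "lat"].to_numpy(),
            geography.loc[cand["zip"], "lon"].to_numpy(),
        )
        d = np.maximum(np.atleast_1d(d), config.floor_miles)
        u = (
            config.theta_distance * np.log(d)
            + config.theta_volume * np.log(cand["latent_attractiveness"].to_numpy())
            + cand[HOSPITAL_COVARIATES].to_numpy(dtype=float) @ theta_cov
        )
        e = np.exp(u - u.max())
        out[zc] = pd.Series(e / e.sum(), index=cand["hospital_id"].to_numpy())
    return out


def generate_patients(
    config: SyntheticConfig, geography: pd.DataFrame, hospitals: pd.DataFrame
) -> pd.DataFrame:
    """Patient table: home ZIPs, logit hospital choices, demographics, deaths."""
    rng = _rng(config, 2)
    n = config.n_patients
    zips = geography.index.to_numpy()
    home = rng.choice(zips, size=n, p=geography["population_weight"].to_numpy())

    probs = choice_probabilities(config, geography, hospitals)
    chosen = np.empty(n, dtype=object)
    for zc in sorted(np.unique(home)):
        idx = np.flatnonzero(home == zc)
        p = probs[zc]
        chosen[idx] = rng.choice(p.index.to_numpy(), size=len(idx), p=p.to_numpy())

    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), AGE_MIN, 100.0)
    sdi = np.clip(rng.normal(SDI_MEAN, SDI_SD, n), 0.0, 100.0)
    sex = rng.choice(["male", "female"], size=n, p=[P_MALE, 1 - P_MALE])
    race = rng.choice(list(P_RACE), size=n, p=list(P_RACE.values()))
    ruca = rng.choice(list(P_RURAL_URBAN), size=n, p=list(P_RURAL_URBAN.values()))
    payer = rng.choice(list(P_PAYER), size=n, p=list(P_PAYER.values()))

    volumes = pd.Series(chosen).value_counts()
    log_v = np.log(volumes.astype(float))
    centered = log_v.loc[chosen].to_numpy() - log_v.mean()
    p_death = expit(MORTALITY_INTERCEPT + MORTALITY_LOG_VOLUME_SLOPE * centered)
    died = rng.random(n) < p_death

    return pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:06d}" for i in range(n)],
            "home_zip": home,
            "hospital_id": chosen,
            "state": geography.loc[home, "state"].to_numpy(),
            "age": np.round(age, 1),
            "sex": sex,
            "race_ethnicity": race,
            "rural_urban": ruca,
            "payer": payer,
            "sdi": np.round(sdi, 1),
            "died_in_hospital": died,
        }
    )


@dataclass
class SyntheticMarket:
    config: SyntheticConfig
    centroids: pd.DataFrame          # zip-indexed: lat, lon, state, population_weight
    hospitals: pd.DataFrame
    patients: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict:
        """Write the three delimited input tables plus the truth report."""
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "centroids": out / "centroids.csv",
            "hospitals": out / "hospitals.csv",
            "patients": out / "patients.csv",
            "truth": out / "truth.json",
        }
        self.centroids.reset_index()[["zip", "lat", "lon", "state"]].to_csv(
            paths["centroids"], index=False
        )
        hosp = self.hospitals.copy()
        for c in HOSPITAL_COVARIATES:
            hosp[c] = hosp[c].astype(int)
        hosp[["hospital_id", "zip", "state"] + HOSPITAL_COVARIATES].to_csv(
            paths["hospitals"], index=False
        )
        self.patients.to_csv(paths["patients"], index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=2, sort_keys=True))
        return {k: str(v) for k, v in paths.items()}


def truth_report(config: SyntheticConfig) -> dict:
    """All true generator parameters, for recovery tests and provenance."""
    d = dataclasses.asdict(config)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    return {"generator_version": GENERATOR_VERSION, **d}


def generate_market(config: SyntheticConfig) -> SyntheticMarket:
    """Run all generation stages; deterministic given the config seed."""
    geography = generate_geography(config)
    hospitals = generate_hospitals(config, geography)
    patients = generate_patients(config, geography, hospitals)
    return SyntheticMarket(config, geography, hospitals, patients, truth_report(config))
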