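"""Geodesic distance between ZIP-code centroids.

Travel distance is modelled as the great-circle distance between the centroid
of the patient's home ZIP code and the centroid of the hospital's ZIP code,
in statute miles, on a sphere of mean Earth radius.  Distances shorter than a
configurable floor (same-ZIP pairs in particular) are raised to the floor so
that log-distance is always defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Mean Earth radius in statute miles used for every great-circle computation.
EARTH_RADIUS_MILES = 3958.7613

#: Default floor applied to raw centroid distances before taking logs, miles.
DEFAULT_FLOOR_MILES = 0.5


def _validate_coord(name: str, value, lo: float, hi: float) -> None:
    arr = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr < lo) or np.any(arr > hi):
        raise ValueError(
            f"{name} out of range [{lo}, {hi}]: got "
            f"{arr[(~np.isfinite(arr)) | (arr < lo) | (arr > hi)][:5]!r}"
            if arr.ndim else f"{name} out of range [{lo}, {hi}]: got {value!r}"
        )


def haversine_miles(lat1, lon1, lat2, lon2):
    """Great-circle distance in miles between points in decimal degrees.

    Vectorised over array-like inputs; symmetric in argument order and zero
    for identical points.  Raises ``ValueError`` naming the offending field
    when a coordinate is outside the valid WGS84 range.
    """
    _validate_coord("lat1", lat1, -90.0, 90.0)
    _validate_coord("lat2", lat2, -90.0, 90.0)
    _validate_coord("lon1", lon1, -180.0, 180.0)
    _validate_coord("lon2", lon2, -180.0, 180.0)

    phi1, lam1, phi2, lam2 = (
        np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2)
    )
    dphi = phi2 - phi1
    dlam = lam2 - lam1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards rounding just above 1 for near-antipodal pairs
    c = 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    out = EARTH_RADIUS_MILES * c
    if np.ndim(out) == 0:
        return float(out)
    return out


@dataclass
class DistanceMatrix:
    """Dense origin-ZIP x hospital distance matrix in miles, floored.

    Attributes
    ----------
    origin_ids : list of str
        Ordered origin ZIP codes (rows).
    destination_ids : list of str
        Ordered hospital identifiers (columns).
    values : ndarray of shape (n_origins, n_destinations)
        Floored great-circle distances, miles; strictly positive.
    floor_miles : float
        Floor applied to raw distances.
    n_floored : int
        Number of entries raised to the floor.
    """

    origin_ids: list
    destination_ids: list
    values: np.ndarray
    floor_miles: float
    n_floored: int = 0
    _origin_pos: dict = field(init=False, repr=False)
    _dest_pos: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._origin_pos = {z: i for i, z in enumerate(self.origin_ids)}
        self._dest_pos = {h: j for j, h in enumerate(self.destination_ids)}

    def lookup(self, origin_zip: str, hospital_id: str) -> float:
        return float(self.values[self._origin_pos[origin_zip], self._dest_pos[hospital_id]])

    def row(self, origin_zip: str) -> np.ndarray:
        """Distances from one origin ZIP to every destination, matrix order."""
        return self.values[self._origin_pos[origin_zip]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.origin_ids, columns=self.destination_ids)


def build_distance_matrix(
    centroids: pd.DataFrame,
    patient_zips: Iterable[str],
    hospital_zips: Mapping[str, str] | pd.Series,
    floor_miles: float = DEFAULT_FLOOR_MILES,
) -> DistanceMatrix:
    """Materialise the patient-ZIP x hospital distance matrix.

    Parameters
    ----------
    centroids : DataFrame indexed by ZIP with ``lat``/``lon`` columns.
    patient_zips : iterable of origin ZIP codes (deduplicated, order kept).
    hospital_zips : mapping hospital_id -> hospital ZIP code.
    floor_miles : lower bound applied to every raw distance.

    Raises
    ------
    KeyError
        If any referenced ZIP is absent from the centroid table; the message
        lists every unresolved code, nothing is silently dropped.
    """
    if isinstance(hospital_zips, pd.Series):
        hospital_zips = hospital_zips.to_dict()
    origin_ids = list(dict.fromkeys(patient_zips))
    destination_ids = list(hospital_zips.keys())
    needed = set(origin_ids) | set(hospital_zips.values())
    missing = sorted(z for z in needed if z not in centroids.index)
    if missing:
        raise KeyError(f"ZIP codes missing from centroid table: {missing}")

    olat = centroids.loc[origin_ids, "lat"].to_numpy(dtype=float)[:, None]
    olon = centroids.loc[origin_ids, "lon"].to_numpy(dtype=float)[:, None]
    dzips = [hospital_zips[h] for h in destination_ids]
    dlat = centroids.loc[dzips, "lat"].to_numpy(dtype=float)[None, :]
    dlon = centroids.loc[dzips, "lon"].to_numpy(dtype=float)[None, :]

    raw = haversine_miles(olat, olon, dlat, dlon)
    n_floored = int(np.count_nonzero(raw < floor_miles))
    if n_floored:
        logger.info("floored %d distance entries to %.3g miles", n_floored, floor_miles)
    values = np.maximum(raw, floor_miles)
    return DistanceMatrix(origin_ids, destination_ids, values, floor_miles, n_floored)
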