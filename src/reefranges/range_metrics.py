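"""Geographic range-size metric and the logit transform of range size.

Range size of a species is measured as the maximum linear distance: the
greatest great-circle distance (km) between any two occurrence records of
the species.  Distances are spherical (haversine, radius 6,371 km); the
difference from an ellipsoidal geodesic is < 0.6% and immaterial here.

Because ranges are bounded by the largest attainable span of the study
region, range sizes are analysed on the logit scale: the range is rescaled
to a proportion of a reference span ``d_ref`` and squeezed away from the
{0, 1} boundary by ``eps`` so that point-range species stay finite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Mean Earth radius in km used throughout; half its circumference
#: (pi * R ~ 20,015 km) is the supremum of the metric.
EARTH_RADIUS_KM = 6371.0

#: Default reference span for the logit transform: the metric's own upper
#: bound (half the Earth's circumference).  Regional analyses should
#: override it with the region's attainable span.
DEFAULT_D_REF_KM = float(np.pi * EARTH_RADIUS_KM)

#: Default boundary squeeze for the logit transform.
DEFAULT_EPS = 0.001


def _check_coords(lon, lat) -> tuple[np.ndarray, np.ndarray]:
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if not (np.all(np.isfinite(lon)) and np.all(np.isfinite(lat))):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(lon) > 180.0) or np.any(np.abs(lat) > 90.0):
        raise ValueError("longitude must lie in [-180, 180] and latitude in [-90, 90]")
    return lon, lat


def geodesic_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between points given in degrees.

    Uses the haversine formulation, which is numerically stable for both
    nearby and antipodal points.  Accepts scalars or broadcastable arrays.
    """
    lon1, lat1 = _check_coords(lon1, lat1)
    lon2, lat2 = _check_coords(lon2, lat2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def max_linear_distance(lon, lat, radius_km: float = EARTH_RADIUS_KM) -> float:
    """Maximum pairwise great-circle distance (km) among a set of records.

    This is a deliberate O(n^2) scan over all unordered pairs — species
    record counts are small, and the brute force IS the definition any
    shortcut must reproduce.  A single record gives 0.
    """
    lon, lat = _check_coords(lon, lat)
    lon, lat = np.atleast_1d(lon), np.atleast_1d(lat)
    if lon.size == 0:
        raise ValueError("max_linear_distance requires at least one record")
    if lon.size == 1:
        return 0.0
    phi = np.radians(lat)
    lam = np.radians(lon)
    # pairwise haversine via broadcasting
    a = (
        np.sin((phi[:, None] - phi[None, :]) / 2.0) ** 2
        + np.cos(phi[:, None]) * np.cos(phi[None, :])
        * np.sin((lam[:, None] - lam[None, :]) / 2.0) ** 2
    )
    d = 2.0 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d.max())


def range_table(
    occurrences: pd.DataFrame,
    d_ref_km: float = DEFAULT_D_REF_KM,
    eps: float = DEFAULT_EPS,
    radius_km: float = EARTH_RADIUS_KM,
) -> pd.DataFrame:
    """Per-species range sizes and logit-transformed response.

    Parameters
    ----------
    occurrences
        DataFrame with columns ``species_id``, ``lon``, ``lat`` (degrees).

    Returns
    -------
    DataFrame with columns ``species_id``, ``range_km``, ``y_logit``,
    one row per species, sorted by species_id.
    """
    required = {"species_id", "lon", "lat"}
    missing = required - set(occurrences.columns)
    if missing:
        raise ValueError(f"occurrence table missing columns: {sorted(missing)}")
    rows = []
    for sp, grp in occurrences.groupby("species_id", sort=True):
        rkm = max_linear_distance(grp["lon"].to_numpy(), grp["lat"].to_numpy(), radius_km)
        rows.append((sp, rkm, logit_transform(rkm, d_ref_km, eps)))
    return pd.DataFrame(rows, columns=["species_id", "range_km", "y_logit"])


def logit_transform(range_km, d_ref: float = DEFAULT_D_REF_KM, eps: float = DEFAULT_EPS):
    """Boundary-squeezed logit of range size.

    ``p = (range_km / d_ref) * (1 - 2 eps) + eps``, returned as
    ``log(p / (1 - p))``.  Strictly increasing in range_km.
    """
    if d_ref <= 0:
        raise ValueError("d_ref must be positive")
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    r = np.asarray(range_km, dtype=float)
    if np.any(r < 0) or np.any(r > d_ref):
        raise ValueError("range_km must lie in [0, d_ref]")
    p = (r / d_ref) * (1.0 - 2.0 * eps) + eps
    y = np.log(p / (1.0 - p))
    return float(y) if np.ndim(range_km) == 0 else y


def inverse_logit_transform(y, d_ref: float = DEFAULT_D_REF_KM, eps: float = DEFAULT_EPS):
    """Inverse of :func:`logit_transform`; recovers range_km."""
    if d_ref <= 0:
        raise ValueError("d_ref must be positive")
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must lie in (0, 0.5)")
    y = np.asarray(y, dtype=float)
    p = 1.0 / (1.0 + np.exp(-y))
    r = (p - eps) / (1.0 - 2.0 * eps) * d_ref
    return float(r) if np.ndim(r) == 0 else r
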