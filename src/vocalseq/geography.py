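"""Geodesic distances and Mantel matrix-correlation tests.

Birds within a study site are separated by tens of metres to a few
kilometres, so great-circle approximations on a spherical Earth are
avoided in favour of the WGS84 ellipsoid: :func:`geodesic_distance`
implements Vincenty's inverse formula (accurate to well under a metre at
these scales). Inter-population distances computed elsewhere (e.g.
resistance-weighted least-cost paths over a habitat model) are consumed
as a pre-computed labelled matrix, never recomputed here.

The Mantel test correlates the lower triangles of two conformable
matrices and builds its null by jointly permuting rows and columns of the
second matrix (Monte-Carlo, one-sided by default with the +1 convention).
When the first matrix holds similarities and the second distances, a
*negative* r means nearby birds sing more similar sequences; similarities
are not silently converted to dissimilarities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

# WGS84 ellipsoid
_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_WGS84_B = _WGS84_A * (1.0 - _WGS84_F)


def geodesic_distance(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """WGS84 geodesic distance in metres (Vincenty inverse formula).

    Falls back to the antipodal-safe great-circle value in the rare case
    the iteration fails to converge.
    """
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    L = math.radians(lon2 - lon1)
    U1 = math.atan((1 - _WGS84_F) * math.tan(phi1))
    U2 = math.atan((1 - _WGS84_F) * math.tan(phi2))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)
    lam = L
    for _ in range(200):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(
            cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
        )
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha**2
        cos_2sigma_m = (
            cos_sigma - 2.0 * sinU1 * sinU2 / cos2_alpha if cos2_alpha != 0 else 0.0
        )
        C = _WGS84_F / 16.0 * cos2_alpha * (4 + _WGS84_F * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = L + (1 - C) * _WGS84_F * sin_alpha * (
            sigma
            + C
            * sin_sigma
            * (cos_2sigma_m + C * cos_sigma * (-1 + 2 * cos_2sigma_m**2))
        )
        if abs(lam - lam_prev) < 1e-12:
            break
    else:  # pragma: no cover - near-antipodal points only
        R = (2 * _WGS84_A + _WGS84_B) / 3.0
        d = math.acos(
            max(-1.0, min(1.0, math.sin(phi1) * math.sin(phi2)
                          + math.cos(phi1) * math.cos(phi2) * math.cos(L)))
        )
        return R * d
    u2 = cos2_alpha * (_WGS84_A**2 - _WGS84_B**2) / _WGS84_B**2
    A = 1 + u2 / 16384.0 * (4096 + u2 * (-768 + u2 * (320 - 175 * u2)))
    Bc = u2 / 1024.0 * (256 + u2 * (-128 + u2 * (74 - 47 * u2)))
    delta_sigma = (
        Bc
        * sin_sigma
        * (
            cos_2sigma_m
            + Bc
            / 4.0
            * (
                cos_sigma * (-1 + 2 * cos_2sigma_m**2)
                - Bc
                / 6.0
                * cos_2sigma_m
                * (-3 + 4 * sin_sigma**2)
                * (-3 + 4 * cos_2sigma_m**2)
            )
        )
    )
    return _WGS84_B * A * (sigma - delta_sigma)


def geodesic_matrix(
    coordinates: Mapping[str, Tuple[float, float]],
    ids: Optional[Sequence[str]] = None,
) -> Tuple[np.ndarray, list[str]]:
    """Pairwise WGS84 geodesic distance matrix (metres) over labelled points.

    Birds listed in ``ids`` but missing from ``coordinates`` are excluded
    with a warning. Returns the matrix and the retained id order.
    """
    import logging

    wanted = list(ids) if ids is not None else list(coordinates)
    kept = [i for i in wanted if i in coordinates]
    missing = [i for i in wanted if i not in coordinates]
    if missing:
        logging.getLogger(__name__).warning(
            "excluding %d birds without coordinates: %s", len(missing), missing
        )
    n = len(kept)
    m = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d = geodesic_distance(*coordinates[kept[a]], *coordinates[kept[b]])
            m[a, b] = m[b, a] = d
    return m, kept


@dataclass
class MantelResult:
    """Matrix correlation with its Monte-Carlo permutation probability."""

    r: float
    r_squared: float
    p: float
    p_two_sided: float
    n: int  # number of objects (matrix rows)
    n_perm: int
    alternative: str


def mantel_test(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    *,
    alternative: str = "greater",
) -> MantelResult:
    """Monte-Carlo Mantel test between two square symmetric matrices.

    ``r`` is the Pearson correlation over lower-triangle entries; the null
    jointly permutes rows and columns of ``m2``. ``alternative`` is
    ``"greater"`` (default: null counts r* >= r_obs), ``"less"`` or
    ``"two-sided"``; a two-sided p is always reported alongside. All
    p-values use the (count + 1) / (n_perm + 1) convention.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ValueError("matrices must be square and conformable")
    n = m1.shape[0]
    if n < 3:
        raise ValueError("Mantel test needs at least 3 rows")
    if not (np.allclose(m1, m1.T) and np.allclose(m2, m2.T)):
        raise ValueError("matrices must be symmetric")
    il = np.tril_indices(n, k=-1)
    x = m1[il]
    if np.ptp(x) == 0 or np.ptp(m2[il]) == 0:
        raise ValueError("constant matrix: Mantel r undefined")

    x = (x - x.mean()) / x.std()

    def corr(mat: np.ndarray) -> float:
        y = mat[il]
        sd = y.std()
        if sd == 0:
            return math.nan
        return float((x * (y - y.mean()) / sd).mean())

    r_obs = corr(m2)
    rng = np.random.default_rng(seed)
    ge = le = extreme = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_star = corr(m2[np.ix_(perm, perm)])
        if math.isnan(r_star):
            continue
        if r_star >= r_obs - 1e-15:
            ge += 1
        if r_star <= r_obs + 1e-15:
            le += 1
        if abs(r_star) >= abs(r_obs) - 1e-15:
            extreme += 1
    p_greater = (ge + 1) / (n_perm + 1)
    p_less = (le + 1) / (n_perm + 1)
    p_two = (extreme + 1) / (n_perm + 1)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = p_two
    else:
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    return MantelResult(
        r=r_obs,
        r_squared=r_obs**2,
        p=p,
        p_two_sided=p_two,
        n=n,
        n_perm=n_perm,
        alternative=alternative,
    )
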