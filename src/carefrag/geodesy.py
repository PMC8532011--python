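"""Geodesic distance on the WGS-84 ellipsoid.

The selection constraint compares the straight-line ("ellipsoid
great-circle") distance between a patient's home and each in-system
hospital against a threshold ``d`` in kilometers. The distance is computed
with Vincenty's inverse iteration on WGS-84. Vincenty's method fails to
converge for nearly antipodal points; in that case we fall back to a
numerical geodesic solver (shooting on the exact geodesic ODE) and flag
the result.

:func:`ode_direct` integrates the geodesic equations

    dphi/ds    = cos(alpha) / M(phi)
    dlambda/ds = sin(alpha) / (N(phi) cos(phi))
    dalpha/ds  = sin(alpha) tan(phi) / N(phi)

with a high-order adaptive integrator. It is algorithmically independent
of Vincenty's series and doubles as the test oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .errors import GeodesyError

# WGS-84
WGS84_A = 6_378_137.0
WGS84_F = 1.0 / 298.257223563
WGS84_B = WGS84_A * (1.0 - WGS84_F)
_E2 = WGS84_F * (2.0 - WGS84_F)  # first eccentricity squared

VINCENTY_TOL = 1e-12
VINCENTY_MAX_ITER = 200


@dataclass(frozen=True)
class GeoPoint:
    lat: float
    lon: float

    def __post_init__(self):
        if not (-90.0 <= self.lat <= 90.0):
            raise GeodesyError(f"latitude {self.lat} outside [-90, 90]")
        if not (-180.0 <= self.lon <= 180.0):
            raise GeodesyError(f"longitude {self.lon} outside [-180, 180]")


@dataclass(frozen=True)
class DistanceResult:
    meters: float
    converged: bool
    iterations: int
    # forward azimuth at the first point (degrees); lets an independent
    # direct solver re-trace the geodesic and bound the distance error
    initial_azimuth_deg: float = float("nan")


def vincenty_inverse(a: GeoPoint, b: GeoPoint,
                     tol: float = VINCENTY_TOL,
                     max_iter: int = VINCENTY_MAX_ITER) -> DistanceResult:
    """Geodesic distance between two points by Vincenty's inverse method.

    Symmetric in its arguments. On non-convergence (near-antipodal pairs)
    falls back to the ODE shooting solver and returns ``converged=False``.
    """
    if a.lat == b.lat and a.lon == b.lon:
        return DistanceResult(0.0, True, 0, 0.0)

    # canonical argument order: both call orders then execute identical
    # floating-point arithmetic, making d(a, b) == d(b, a) bit-exact; the
    # azimuth at `a` is recovered from the reverse azimuth when swapped
    swapped = (b.lat, b.lon) < (a.lat, a.lon)
    p, q = (b, a) if swapped else (a, b)

    f = WGS84_F
    L = math.radians(q.lon - p.lon)
    U1 = math.atan((1.0 - f) * math.tan(math.radians(p.lat)))
    U2 = math.atan((1.0 - f) * math.tan(math.radians(q.lat)))
    sinU1, cosU1 = math.sin(U1), math.cos(U1)
    sinU2, cosU2 = math.sin(U2), math.cos(U2)

    lam = L
    for iteration in range(1, max_iter + 1):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cosU2 * sin_lam,
                               cosU1 * sinU2 - sinU1 * cosU2 * cos_lam)
        if sin_sigma == 0.0:
            return DistanceResult(0.0, True, iteration)  # coincident
        cos_sigma = sinU1 * sinU2 + cosU1 * cosU2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cosU1 * cosU2 * sin_lam / sin_sigma
        cos_sq_alpha = 1.0 - sin_alpha * sin_alpha
        if cos_sq_alpha == 0.0:
            cos_2sigma_m = 0.0  # equatorial line
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sinU1 * sinU2 / cos_sq_alpha
        C = f / 16.0 * cos_sq_alpha * (4.0 + f * (4.0 - 3.0 * cos_sq_alpha))
        lam_prev = lam
        lam = L + (1.0 - C) * f * sin_alpha * (
            sigma + C * sin_sigma * (
                cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
            )
        )
        if abs(lam - lam_prev) < tol:
            u_sq = cos_sq_alpha * (WGS84_A ** 2 - WGS84_B ** 2) / WGS84_B ** 2
            A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
            B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
            delta_sigma = B * sin_sigma * (
                cos_2sigma_m + B / 4.0 * (
                    cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
                    - B / 6.0 * cos_2sigma_m
                    * (-3.0 + 4.0 * sin_sigma ** 2)
                    * (-3.0 + 4.0 * cos_2sigma_m ** 2)
                )
            )
            if swapped:
                # forward azimuth at q along p->q, reversed to point q->p
                alpha = math.atan2(
                    cosU1 * sin_lam,
                    -sinU1 * cosU2 + cosU1 * sinU2 * cos_lam,
                ) + math.pi
            else:
                alpha = math.atan2(
                    cosU2 * sin_lam, cosU1 * sinU2 - sinU1 * cosU2 * cos_lam
                )
            return DistanceResult(
                WGS84_B * A * (sigma - delta_sigma), True, iteration,
                math.degrees(alpha) % 360.0,
            )

    meters, azimuth = _shoot_inverse(p, q)
    return DistanceResult(meters, False, max_iter,
                          (azimuth + (180.0 if swapped else 0.0)) % 360.0)


def vincenty_direct(start: GeoPoint, azimuth_deg: float, distance_m: float) -> GeoPoint:
    """Direct geodesic problem by Vincenty's direct formula (fast; used by
    the synthetic generator to place homes at sampled distances/bearings)."""
    if distance_m == 0.0:
        return start
    f = WGS84_F
    alpha1 = math.radians(azimuth_deg)
    sin_alpha1, cos_alpha1 = math.sin(alpha1), math.cos(alpha1)
    tanU1 = (1.0 - f) * math.tan(math.radians(start.lat))
    cosU1 = 1.0 / math.sqrt(1.0 + tanU1 ** 2)
    sinU1 = tanU1 * cosU1
    sigma1 = math.atan2(tanU1, cos_alpha1)
    sin_alpha = cosU1 * sin_alpha1
    cos_sq_alpha = 1.0 - sin_alpha ** 2
    u_sq = cos_sq_alpha * (WGS84_A ** 2 - WGS84_B ** 2) / WGS84_B ** 2
    A = 1.0 + u_sq / 16384.0 * (4096.0 + u_sq * (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    B = u_sq / 1024.0 * (256.0 + u_sq * (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))

    sigma = distance_m / (WGS84_B * A)
    for _ in range(200):
        cos_2sigma_m = math.cos(2.0 * sigma1 + sigma)
        sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
        delta_sigma = B * sin_sigma * (
            cos_2sigma_m + B / 4.0 * (
                cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
                - B / 6.0 * cos_2sigma_m
                * (-3.0 + 4.0 * sin_sigma ** 2)
                * (-3.0 + 4.0 * cos_2sigma_m ** 2)
            )
        )
        sigma_prev = sigma
        sigma = distance_m / (WGS84_B * A) + delta_sigma
        if abs(sigma - sigma_prev) < 1e-13:
            break
    sin_sigma, cos_sigma = math.sin(sigma), math.cos(sigma)
    cos_2sigma_m = math.cos(2.0 * sigma1 + sigma)
    tmp = sinU1 * sin_sigma - cosU1 * cos_sigma * cos_alpha1
    phi2 = math.atan2(
        sinU1 * cos_sigma + cosU1 * sin_sigma * cos_alpha1,
        (1.0 - f) * math.hypot(sin_alpha, tmp),
    )
    lam = math.atan2(sin_sigma * sin_alpha1,
                     cosU1 * cos_sigma - sinU1 * sin_sigma * cos_alpha1)
    C = f / 16.0 * cos_sq_alpha * (4.0 + f * (4.0 - 3.0 * cos_sq_alpha))
    L = lam - (1.0 - C) * f * sin_alpha * (
        sigma + C * sin_sigma * (
            cos_2sigma_m + C * cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
        )
    )
    lon = start.lon + math.degrees(L)
    if lon > 180.0:
        lon -= 360.0
    elif lon < -180.0:
        lon += 360.0
    return GeoPoint(math.degrees(phi2), lon)


def _radii(phi: float) -> tuple[float, float]:
    """Meridional (M) and prime-vertical (N) curvature radii at latitude phi."""
    s2 = math.sin(phi) ** 2
    w = math.sqrt(1.0 - _E2 * s2)
    return WGS84_A * (1.0 - _E2) / w ** 3, WGS84_A / w


def _geodesic_rhs(_s, y):
    phi, _lam, alpha = y
    M, N = _radii(phi)
    cphi = math.cos(phi)
    return [
        math.cos(alpha) / M,
        math.sin(alpha) / (N * cphi),
        math.sin(alpha) * math.tan(phi) / N,
    ]


def ode_direct(start: GeoPoint, azimuth_deg: float, distance_m: float,
               rtol: float = 1e-12, atol: float = 1e-12) -> GeoPoint:
    """Direct geodesic problem by numerical integration of the geodesic ODE.

    Independent of Vincenty's series expansion; accuracy is governed by the
    integrator tolerances (default well below a millimeter for continental
    distances, away from the poles).
    """
    if distance_m == 0.0:
        return start
    y0 = [math.radians(start.lat), math.radians(start.lon), math.radians(azimuth_deg)]
    sol = solve_ivp(_geodesic_rhs, (0.0, distance_m), y0,
                    method="DOP853", rtol=rtol, atol=atol, dense_output=False)
    if not sol.success:
        raise GeodesyError(f"geodesic ODE integration failed: {sol.message}")
    phi, lam = sol.y[0, -1], sol.y[1, -1]
    lon = math.degrees(lam)
    if lon > 180.0:
        lon -= 360.0
    elif lon < -180.0:
        lon += 360.0
    return GeoPoint(math.degrees(phi), lon)


def _spherical_initial(a: GeoPoint, b: GeoPoint) -> tuple[float, float]:
    """Great-circle azimuth (deg) and distance (m) on the mean sphere."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dlon = math.radians(b.lon - a.lon)
    y = math.sin(dlon) * math.cos(phi2)
    x = math.cos(phi1) * math.sin(phi2) - math.sin(phi1) * math.cos(phi2) * math.cos(dlon)
    az = math.degrees(math.atan2(y, x))
    central = math.atan2(
        math.hypot(y, math.sin(phi2) * math.cos(phi1)
                   - math.cos(phi2) * math.sin(phi1) * math.cos(dlon) + 0.0),
        math.sin(phi1) * math.sin(phi2) + math.cos(phi1) * math.cos(phi2) * math.cos(dlon),
    )
    r_mean = (2.0 * WGS84_A + WGS84_B) / 3.0
    return az, central * r_mean


def _shoot_inverse(a: GeoPoint, b: GeoPoint) -> float:
    """Inverse problem by shooting on (azimuth, arclength). Slow; used only
    as the fallback when Vincenty's iteration does not converge."""
    az0, s0 = _spherical_initial(a, b)
    target = np.array([math.radians(b.lat), math.radians(b.lon)])

    def miss(params):
        az, s = params
        p = ode_direct(a, az, max(s, 1.0), rtol=1e-11, atol=1e-11)
        dlam = math.radians(p.lon) - target[1]
        dlam = (dlam + math.pi) % (2.0 * math.pi) - math.pi
        return [math.radians(p.lat) - target[0], dlam * math.cos(target[0])]

    res = least_squares(miss, x0=[az0, max(s0, 1.0)], xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise GeodesyError("fallback geodesic solver failed to converge")
    return float(res.x[1]), float(res.x[0])


def min_hospital_distance_km(home: GeoPoint, hospitals) -> float:
    """Minimum geodesic distance (km) from ``home`` to any in-system hospital.

    ``hospitals`` is a facilities table (DataFrame with ``lat``/``lon`` and
    ``in_system``/``is_hospital`` flags) or an iterable of :class:`GeoPoint`.
    """
    points: list[GeoPoint] = []
    if hasattr(hospitals, "itertuples"):
        for row in hospitals.itertuples():
            if hasattr(row, "in_system") and not (row.in_system and row.is_hospital):
                raise GeodesyError(
                    f"facility {getattr(row, 'facility_id', '?')} is not an in-system hospital"
                )
            points.append(GeoPoint(float(row.lat), float(row.lon)))
    else:
        points = [p if isinstance(p, GeoPoint) else GeoPoint(*p) for p in hospitals]
    if not points:
        raise GeodesyError("hospital list is empty")
    return min(vincenty_inverse(home, p).meters for p in points) / 1000.0
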