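"""Geodesic distance on the WGS84 ellipsoid (Vincenty inverse formula)."""

from __future__ import annotations

import math

WGS84_A = 6378137.0                    # semi-major axis, m
WGS84_F = 1.0 / 298.257223563          # flattening
WGS84_B = WGS84_A * (1.0 - WGS84_F)


class GeodesicConvergenceError(RuntimeError):
    pass


def vincenty_m(lat1: float, lon1: float, lat2: float, lon2: float,
               tol: float = 1e-12, max_iter: int = 200) -> float:
    """Geodesic distance in metres between two WGS84 points.

    Iterative inverse solution; raises :class:`GeodesicConvergenceError` for
    the nearly antipodal cases where the classical iteration diverges.
    """
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    if lat1 == lat2 and (lon1 - lon2) % 360.0 == 0.0:
        return 0.0

    a, b, f = WGS84_A, WGS84_B, WGS84_F
    u1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    u2 = math.atan((1 - f) * math.tan(math.radians(lat2)))
    big_l = math.radians(lon2 - lon1)
    sin_u1, cos_u1 = math.sin(u1), math.cos(u1)
    sin_u2, cos_u2 = math.sin(u2), math.cos(u2)

    lam = big_l
    for _ in range(max_iter):
        sin_lam, cos_lam = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cos_u2 * sin_lam,
                               cos_u1 * sin_u2 - sin_u1 * cos_u2 * cos_lam)
        if sin_sigma == 0.0:
            return 0.0
        cos_sigma = sin_u1 * sin_u2 + cos_u1 * cos_u2 * cos_lam
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cos_u1 * cos_u2 * sin_lam / sin_sigma
        cos2_alpha = 1.0 - sin_alpha * sin_alpha
        if cos2_alpha == 0.0:                 # equatorial line
            cos_2sigma_m = 0.0
        else:
            cos_2sigma_m = cos_sigma - 2.0 * sin_u1 * sin_u2 / cos2_alpha
        c = f / 16.0 * cos2_alpha * (4.0 + f * (4.0 - 3.0 * cos2_alpha))
        lam_prev = lam
        lam = big_l + (1.0 - c) * f * sin_alpha * (
            sigma + c * sin_sigma * (
                cos_2sigma_m + c * cos_sigma *
                (-1.0 + 2.0 * cos_2sigma_m * cos_2sigma_m)))
        if abs(lam - lam_prev) < tol:
            break
    else:
        raise GeodesicConvergenceError(
            f"Vincenty failed to converge for ({lat1},{lon1})-({lat2},{lon2})")

    u_sq = cos2_alpha * (a * a - b * b) / (b * b)
    big_a = 1 + u_sq / 16384.0 * (4096.0 + u_sq *
                                  (-768.0 + u_sq * (320.0 - 175.0 * u_sq)))
    big_b = u_sq / 1024.0 * (256.0 + u_sq *
                             (-128.0 + u_sq * (74.0 - 47.0 * u_sq)))
    delta_sigma = big_b * sin_sigma * (
        cos_2sigma_m + big_b / 4.0 * (
            cos_sigma * (-1.0 + 2.0 * cos_2sigma_m ** 2)
            - big_b / 6.0 * cos_2sigma_m * (-3.0 + 4.0 * sin_sigma ** 2)
            * (-3.0 + 4.0 * cos_2sigma_m ** 2)))
    return b * big_a * (sigma - delta_sigma)


def vincenty_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    return vincenty_m(lat1, lon1, lat2, lon2) / 1000.0
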