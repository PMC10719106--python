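"""Great-circle distances: participant access to the nearest district clinic."""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

__all__ = ["EARTH_RADIUS_KM", "great_circle_km", "nearest_clinic_km"]

EARTH_RADIUS_KM = 6371.0


def _check(lat: float, lon: float) -> None:
    if not (math.isfinite(lat) and math.isfinite(lon)):
        raise ValueError("coordinates must be finite")
    if abs(lat) > 90.0:
        raise ValueError(f"latitude {lat} out of range [-90, 90]")


def great_circle_km(point_a: tuple[float, float], point_b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) pairs in degrees."""
    lat1, lon1 = point_a
    lat2, lon2 = point_b
    _check(lat1, lon1)
    _check(lat2, lon2)
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def nearest_clinic_km(
    point: tuple[float, float], clinics: Sequence[tuple[float, float]]
) -> float:
    """Distance from a participant to the closest clinic in ``clinics``."""
    if len(clinics) == 0:
        raise ValueError("need at least one clinic")
    return float(np.min([great_circle_km(point, c) for c in clinics]))
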