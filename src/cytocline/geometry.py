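"""Transect geometry: great-circle distances and scaled transect positions.

All clines in this package are fitted on a scaled transect distance in
[0, 1]: the great-circle distance of each sample from an anchor sample
(by default the westernmost one, standing in for "closest to the coast"
in a hybrid zone that runs east from the Pacific), min-max normalized
within each contact zone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0  # mean Earth radius


class DegenerateTransectError(ValueError):
    """All samples co-located: no transect axis exists."""


@dataclass(frozen=True)
class TransectPosition:
    sample_id: str
    distance_km: float
    distance_scaled: float

    def __post_init__(self) -> None:
        if self.distance_km < 0:
            raise ValueError(f"negative distance for {self.sample_id}")
        if not (0.0 <= self.distance_scaled <= 1.0):
            raise ValueError(f"scaled distance outside [0,1] for {self.sample_id}")


def _check_coord(lat: float, lon: float) -> None:
    if not (-90.0 <= lat <= 90.0):
        raise ValueError(f"latitude {lat} outside [-90, 90]")
    if not (-180.0 <= lon <= 180.0):
        raise ValueError(f"longitude {lon} outside [-180, 180]")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two points in decimal degrees."""
    _check_coord(lat1, lon1)
    _check_coord(lat2, lon2)
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    # clip guards rounding at antipodes
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0))))


def scale_transect(
    samples: Sequence[tuple[str, float, float]],
    anchor_rule: str = "westernmost",
) -> list[TransectPosition]:
    """Distance of each sample from the anchor, min-max scaled to [0, 1].

    Parameters
    ----------
    samples
        Sequence of ``(sample_id, lat, lon)`` tuples for one contact zone.
    anchor_rule
        ``"westernmost"`` (minimum longitude, ties broken by sample id) or
        an explicit sample id present in ``samples``.

    Raises
    ------
    DegenerateTransectError
        If fewer than two distinct locations exist (max distance is zero).
    """
    if len(samples) < 2:
        raise DegenerateTransectError("need at least two samples to define a transect")
    ids = [s[0] for s in samples]
    if anchor_rule == "westernmost":
        anchor = min(samples, key=lambda s: (s[2], s[0]))
    else:
        try:
            anchor = samples[ids.index(anchor_rule)]
        except ValueError:
            raise ValueError(f"anchor sample {anchor_rule!r} not found") from None
    dists = np.array([haversine_km(anchor[1], anchor[2], s[1], s[2]) for s in samples])
    dmax = dists.max()
    if dmax == 0.0:
        raise DegenerateTransectError("all samples co-located; transect undefined")
    scaled = dists / dmax
    return [
        TransectPosition(sid, float(d), float(x))
        for sid, d, x in zip(ids, dists, scaled)
    ]
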