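"""Habitat suitability to landscape resistance.

Movement cost is assumed to decline exponentially with habitat suitability:
good habitat is nearly free to traverse while only very poor habitat is
strongly resistant.  The transform is

    raw = 1000 ** (-HS)

followed by a linear rescale of the raw range [1000^-1, 1000^0] onto
[1, 100], so R = 1 exactly when HS = 1 and R = 100 exactly when HS = 0.
The convexity of the base-1000 exponential means most of the suitability
range maps to low resistance (R < 10 for all HS > ~0.35).
"""

from __future__ import annotations

import hashlib

import numpy as np

from .raster import RasterGrid

__all__ = ["suitability_to_resistance", "resistance_value"]

_RAW_LO = 1000.0 ** -1
_RAW_HI = 1.0


def resistance_value(hs: np.ndarray | float, base: float = 1000.0):
    """Scalar/array form of the transform (exponent base configurable)."""
    hs = np.asarray(hs, dtype=float)
    raw = base ** (-hs)
    lo, hi = base ** -1.0, 1.0
    return 1.0 + 99.0 * (raw - lo) / (hi - lo)


def suitability_to_resistance(hs_surface: RasterGrid,
                              base: float = 1000.0) -> RasterGrid:
    """Resistance surface R in [1, 100] from a suitability surface in [0, 1].

    Raises ``ValueError`` if any valid cell lies outside [0, 1]; nodata
    propagates.  The result carries ``provenance``, a SHA-256 digest of the
    source suitability values.
    """
    vals = hs_surface.values
    m = hs_surface.mask
    if m.any() and (np.nanmin(vals) < 0 or np.nanmax(vals) > 1):
        raise ValueError("habitat suitability must lie in [0, 1]")
    out = np.full(hs_surface.shape, np.nan)
    out[m] = resistance_value(vals[m], base=base)
    grid = hs_surface.like(out)
    grid.provenance = hashlib.sha256(
        np.ascontiguousarray(vals).tobytes()).hexdigest()
    return grid
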