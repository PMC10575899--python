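"""Spectral signatures and endmember sets.

A signature is the six-component vector used throughout the unmixing model:
surface reflectance in blue, green, red and near-infrared, plus the two
derived band-ratio indices NDVI = (nir - red)/(nir + red) and
NDWI = (green - nir)/(green + nir) (McFeeters form).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: order of the signature vector components
BANDS = ("blue", "green", "red", "nir")
COMPONENTS = BANDS + ("ndvi", "ndwi")


def ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """NDVI with zero-denominator cells set to 0."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = nir + red
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (nir - red) / np.where(denom > 0, denom, 1.0), 0.0)
    return out


def ndwi(green: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """NDWI (green vs. near-infrared) with zero-denominator cells set to 0."""
    green = np.asarray(green, dtype=float)
    nir = np.asarray(nir, dtype=float)
    denom = green + nir
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0, (green - nir) / np.where(denom > 0, denom, 1.0), 0.0)
    return out


@dataclass(frozen=True)
class SpectralSignature:
    """One six-component signature (reflectances in [0, 1])."""

    blue: float
    green: float
    red: float
    nir: float
    ndvi: float = field(default=None)  # type: ignore[assignment]
    ndwi: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ndvi is None:
            object.__setattr__(self, "ndvi", float(ndvi(self.nir, self.red)))
        if self.ndwi is None:
            object.__setattr__(self, "ndwi", float(ndwi(self.green, self.nir)))
        for b in BANDS:
            v = getattr(self, b)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise ValueError(f"reflectance {b}={v} outside [0, 1]")

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in COMPONENTS], dtype=float)

    def band_vector(self) -> np.ndarray:
        return np.array([getattr(self, b) for b in BANDS], dtype=float)


@dataclass(frozen=True)
class EndmemberSet:
    """Vegetation / impervious / water endmember basis (n = 3).

    Class constraints: vegetation NDVI > 0.8, impervious NDVI < 0.2,
    water NDWI > 0; the three signatures must be linearly independent.
    """

    vegetation: SpectralSignature
    impervious: SpectralSignature
    water: SpectralSignature

    def __post_init__(self) -> None:
        if not self.vegetation.ndvi > 0.8:
            raise ValueError(f"vegetation NDVI {self.vegetation.ndvi:.3f} not > 0.8")
        if not self.impervious.ndvi < 0.2:
            raise ValueError(f"impervious NDVI {self.impervious.ndvi:.3f} not < 0.2")
        if not self.water.ndwi > 0:
            raise ValueError(f"water NDWI {self.water.ndwi:.3f} not > 0")
        if np.linalg.matrix_rank(self.band_matrix()) < 3:
            raise ValueError("endmember band signatures are linearly dependent")

    @property
    def n(self) -> int:
        return 3

    @property
    def members(self) -> tuple[SpectralSignature, SpectralSignature, SpectralSignature]:
        return (self.vegetation, self.impervious, self.water)

    def matrix(self) -> np.ndarray:
        """(6, 3) matrix of full signatures, columns ordered veg/imp/water."""
        return np.stack([m.as_vector() for m in self.members], axis=1)

    def band_matrix(self) -> np.ndarray:
        """(4, 3) matrix of band reflectances only."""
        return np.stack([m.band_vector() for m in self.members], axis=1)
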