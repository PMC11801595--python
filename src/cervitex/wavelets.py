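"""Level-3 separable 2-D discrete wavelet decomposition of image tiles.

Sixteen wavelet families are supported (four each from the Daubechies,
biorthogonal, Coiflet and Symlet families).  A 256x256 tile decomposed to
level 3 under periodization boundary handling yields four 32x32 sub-bands:
the approximation CA and the horizontal/vertical/diagonal details CD1, CD2,
CD3 produced at the coarsest stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from cervitex.image_io import GrayImage

#: The supported families in the canonical reporting-column order.
WAVELET_FAMILIES = (
    "db2", "db3", "db4", "db5",
    "bior1.5", "bior1.3", "bior2.8", "bior3.3",
    "coif2", "coif3", "coif4", "coif5",
    "sym2", "sym3", "sym4", "sym5",
)


class SpecError(ValueError):
    """Raised for a wavelet family/level outside the supported set."""


class DecompositionError(ValueError):
    """Raised when an input cannot be decomposed at the requested level."""


def list_supported_wavelets() -> list[str]:
    """Return the 16 supported wavelet family names in canonical order."""
    return list(WAVELET_FAMILIES)


@dataclass(frozen=True)
class WaveletSpec:
    """A named wavelet family with decomposition level and boundary mode."""

    family: str
    level: int = 3
    mode: str = "periodization"

    def __post_init__(self) -> None:
        if self.family not in WAVELET_FAMILIES:
            raise SpecError(f"unsupported wavelet family {self.family!r}; "
                            f"choose one of {WAVELET_FAMILIES}")
        if self.level < 1:
            raise SpecError(f"level must be >= 1, got {self.level}")

    @property
    def wavelet(self) -> pywt.Wavelet:
        return pywt.Wavelet(self.family)


@dataclass
class SubbandSet:
    """The four coarsest-stage sub-bands of one tile under one wavelet spec.

    ``ca`` is the level-l approximation; ``cd1``/``cd2``/``cd3`` are the
    horizontal, vertical and diagonal details of the same stage.  The full
    coefficient tree is retained so the decomposition is invertible.
    """

    ca: np.ndarray
    cd1: np.ndarray
    cd2: np.ndarray
    cd3: np.ndarray
    level: int
    spec: WaveletSpec
    coeffs: list = field(repr=False, default=None)

    @property
    def bands(self) -> dict[str, np.ndarray]:
        return {"CA": self.ca, "CD1": self.cd1, "CD2": self.cd2, "CD3": self.cd3}


def _as_array(tile: GrayImage | np.ndarray) -> np.ndarray:
    data = tile.pixels if isinstance(tile, GrayImage) else np.asarray(tile)
    if data.ndim != 2:
        raise DecompositionError(f"expected a 2-D raster, got ndim={data.ndim}")
    return data.astype(np.float64)


def decompose(tile: GrayImage | np.ndarray, spec: WaveletSpec) -> SubbandSet:
    """Iterated separable 2-D DWT of a tile; returns the coarsest-stage bands.

    Pixel data is cast to float64 with no prior normalization.  Under
    periodization each stage halves both dimensions, so a 256x256 tile at
    level 3 yields 32x32 sub-bands.
    """
    data = _as_array(tile)
    max_level = pywt.dwtn_max_level(data.shape, spec.wavelet)
    if spec.level > max_level and spec.mode == "periodization":
        # periodization tolerates short signals as long as halving stays >= 1
        if min(data.shape) < 2 ** spec.level:
            raise DecompositionError(
                f"level {spec.level} too deep for shape {data.shape}")
    coeffs = pywt.wavedec2(data, spec.wavelet, mode=spec.mode, level=spec.level)
    ca = coeffs[0]
    cd1, cd2, cd3 = coeffs[1]  # (horizontal, vertical, diagonal) at level l
    return SubbandSet(ca=ca, cd1=cd1, cd2=cd2, cd3=cd3,
                      level=spec.level, spec=spec, coeffs=coeffs)


def reconstruct(subbands: SubbandSet) -> np.ndarray:
    """Inverse transform from the retained full coefficient tree."""
    if subbands.coeffs is None:
        raise DecompositionError(
            "reconstruction requires the full coefficient tree")
    return pywt.waverec2(subbands.coeffs, subbands.spec.wavelet,
                         mode=subbands.spec.mode)
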