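"""Color chips in CIELAB space, the similarity kernel, and environmental noise.

The universe ``U`` of the color game is a :class:`ChipChart`: an ordered
collection of color chips with 3-D CIELAB coordinates (L*, a*, b*).  Euclidean
distance in CIELAB approximates perceived color difference, and similarity
between chips is the Gaussian kernel ``sim(x, y) = exp(-c * dist(x, y)**2)``
with scaling factor ``c = 0.001``, the standard choice in color-naming studies.
Environmental noise perturbs a chip's coordinates with isotropic Gaussian noise
of variance ``sigma_e_sq`` per component before the sender sees it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ColorChip",
    "ChipChart",
    "SimilarityParams",
    "cielab_distance",
    "similarity",
    "similarity_matrix",
    "perturb_chip",
]


@dataclass(frozen=True)
class ColorChip:
    """A single color chip: an integer id and CIELAB (L*, a*, b*) coordinates.

    ``munsell_hue`` / ``munsell_value`` carry the chart's Munsell codes when
    read from a survey file; they are metadata only.
    """

    chip_id: int
    coords: tuple[float, float, float]
    munsell_hue: str | None = None
    munsell_value: str | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,):
            raise ValueError(f"chip {self.chip_id}: coords must be 3-D, got shape {c.shape}")
        if not np.all(np.isfinite(c)):
            raise ValueError(f"chip {self.chip_id}: coords must be finite, got {self.coords}")
        object.__setattr__(self, "coords", tuple(float(v) for v in c))


@dataclass
class ChipChart:
    """Ordered, non-empty collection of chips with ids ``0..n-1``.

    This is the domain of colors the agents communicate about.  ``coords``
    exposes the chart as an ``(n, 3)`` float array for vectorized use.
    """

    chips: list[ColorChip]
    name: str = "chart"
    _coords: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.chips:
            raise ValueError("a chip chart must contain at least one chip")
        ids = [c.chip_id for c in self.chips]
        if ids != list(range(len(self.chips))):
            raise ValueError("chip_ids must form the contiguous range 0..n-1 in order")
        self._coords = np.array([c.coords for c in self.chips], dtype=float)

    def __len__(self) -> int:
        return len(self.chips)

    def __iter__(self) -> Iterable[ColorChip]:
        return iter(self.chips)

    def __getitem__(self, chip_id: int) -> ColorChip:
        return self.chips[chip_id]

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of CIELAB coordinates, row i = chip i."""
        return self._coords

    @classmethod
    def from_coords(cls, coords: Sequence[Sequence[float]], name: str = "chart") -> "ChipChart":
        chips = [ColorChip(i, tuple(row)) for i, row in enumerate(coords)]
        return cls(chips=chips, name=name)


@dataclass(frozen=True)
class SimilarityParams:
    """Parameters of the similarity kernel; ``scale_c`` is the scaling factor c."""

    scale_c: float = 0.001

    def __post_init__(self) -> None:
        if not self.scale_c > 0:
            raise ValueError(f"scale_c must be positive, got {self.scale_c}")


def cielab_distance(a: ColorChip, b: ColorChip) -> float:
    """Euclidean distance between two chips in CIELAB space."""
    return float(np.linalg.norm(np.asarray(a.coords) - np.asarray(b.coords)))


def similarity(a: ColorChip, b: ColorChip, p: SimilarityParams = SimilarityParams()) -> float:
    """Gaussian similarity ``exp(-c * dist(a, b)**2)``; 1 iff coordinates coincide."""
    d = cielab_distance(a, b)
    return float(np.exp(-p.scale_c * d * d))


def similarity_matrix(chart: ChipChart, p: SimilarityParams = SimilarityParams()) -> np.ndarray:
    """(n, n) matrix of pairwise similarities over the chart (unit diagonal)."""
    x = chart.coords
    sq = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    return np.exp(-p.scale_c * sq)


def perturb_chip(
    chip: ColorChip, sigma_e_sq: float, rng: np.random.Generator
) -> np.ndarray:
    """Chip coordinates plus iid Gaussian noise of variance ``sigma_e_sq`` per component.

    Variance 0 returns the coordinates exactly.  Negative variance is rejected.
    """
    if sigma_e_sq < 0:
        raise ValueError(f"noise variance must be nonnegative, got {sigma_e_sq}")
    coords = np.asarray(chip.coords, dtype=float)
    if sigma_e_sq == 0:
        return coords.copy()
    return coords + rng.normal(0.0, np.sqrt(sigma_e_sq), size=3)
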