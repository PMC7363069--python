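"""Synthetic chip charts and planted-partition naming data.

The real survey chart is a 40-hue x 8-value grid of maximally saturated chips
plus 10 achromatic chips.  :func:`make_synthetic_chart` emulates its geometry:
chromatic chips sit on an elliptic cylinder in (a*, b*) — so the hue dimension
wraps smoothly — with L* set by the value row, and achromatic chips run up the
L* axis.  Default ranges are chosen so the per-dimension standard deviations
land near the real chart's (about 23 / 29 / 33 for L*, a*, b*).

:func:`make_planted_language` plants a spatially coherent k-way ground-truth
partition (a correlation clustering of the chart) and simulates speakers who
name each chip with the planted term, except that with probability
``confusion_rate`` they slip to a term of a neighboring category — the kind of
boundary disagreement real informants show.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .color_domain import ChipChart, ColorChip, SimilarityParams
from .corr_clustering import build_similarity_graph, solve
from .partitioning import Partition
from .wcs_io import LanguageNamingData, SpeakerResponses

__all__ = [
    "SyntheticChartSpec",
    "PlantedLanguageSpec",
    "make_synthetic_chart",
    "make_planted_language",
]

DEFAULT_LAB_RANGES = ((15.0, 95.0), (-41.0, 41.0), (-47.0, 47.0))


@dataclass(frozen=True)
class SyntheticChartSpec:
    """Geometry of a synthetic chart; defaults give the standard 330-chip layout."""

    n_hues: int = 40
    n_values: int = 8
    n_achromatic: int = 10
    lab_ranges: tuple = DEFAULT_LAB_RANGES
    seed: int = 0
    jitter_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_hues < 1 or self.n_values < 1 or self.n_achromatic < 0:
            raise ValueError("chart dimensions must be positive (achromatic >= 0)")
        if len(self.lab_ranges) != 3 or any(lo >= hi for lo, hi in self.lab_ranges):
            raise ValueError("lab_ranges must be three (min, max) pairs with min < max")

    @property
    def size(self) -> int:
        return self.n_hues * self.n_values + self.n_achromatic


@dataclass(frozen=True)
class PlantedLanguageSpec:
    """A simulated speech community with a planted k-term color vocabulary."""

    k_terms: int
    confusion_rate: float = 0.1
    n_speakers: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_terms < 2:
            raise ValueError("k_terms must be >= 2")
        if not 0 <= self.confusion_rate < 1:
            raise ValueError("confusion_rate must be in [0, 1)")
        if self.n_speakers < 1:
            raise ValueError("need at least one speaker")


def make_synthetic_chart(spec: SyntheticChartSpec) -> ChipChart:
    """Deterministic (under ``spec.seed``) WCS-like chart of ``spec.size`` chips."""
    rng = np.random.default_rng(spec.seed)
    (l_lo, l_hi), (a_lo, a_hi), (b_lo, b_hi) = spec.lab_ranges
    ra, rb = (a_hi - a_lo) / 2.0, (b_hi - b_lo) / 2.0
    a0, b0 = (a_hi + a_lo) / 2.0, (b_hi + b_lo) / 2.0

    coords = []
    meta = []
    levels = (
        np.linspace(l_lo, l_hi, spec.n_values) if spec.n_values > 1 else [(l_lo + l_hi) / 2]
    )
    for v, lightness in enumerate(levels):
        for h in range(spec.n_hues):
            angle = 2.0 * np.pi * h / spec.n_hues
            coords.append(
                (lightness, a0 + ra * np.cos(angle), b0 + rb * np.sin(angle))
            )
            meta.append((f"H{h}", f"V{v}"))
    for i in range(spec.n_achromatic):
        frac = i / max(spec.n_achromatic - 1, 1)
        coords.append((l_lo + frac * (l_hi - l_lo), a0, b0))
        meta.append(("N", f"A{i}"))

    coords = np.asarray(coords) + rng.normal(0.0, spec.jitter_sd, size=(len(coords), 3))
    chips = [
        ColorChip(i, tuple(c), munsell_hue=m[0], munsell_value=m[1])
        for i, (c, m) in enumerate(zip(coords, meta))
    ]
    return ChipChart(chips=chips, name=f"synthetic-{spec.size}-seed{spec.seed}")


def _planted_partition(chart: ChipChart, k: int, seed: int) -> Partition:
    """Spatially coherent k-way partition: capped correlation clustering, with
    k-means splitting of the largest category if the solver uses fewer than k."""
    rng = np.random.default_rng(seed)
    part, _ = solve(
        build_similarity_graph(chart), restarts=5, rng=rng, max_clusters=k,
        chart_ref=chart.name,
    )
    labels = part.label_array()
    while len(np.unique(labels)) < k:
        groups, counts = np.unique(labels, return_counts=True)
        big = groups[np.argmax(counts)]
        idx = np.flatnonzero(labels == big)
        km = KMeans(n_clusters=2, n_init=3, random_state=seed).fit(chart.coords[idx])
        labels[idx[km.labels_ == 1]] = labels.max() + 1
    return Partition.from_array(labels, chart_ref=chart.name)


def _adjacent_categories(chart: ChipChart, labels: np.ndarray, m_neighbors: int = 10):
    """Per chip: categories of its nearest foreign chips (the slip candidates)."""
    x = chart.coords
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    adj = []
    for c in range(len(chart)):
        order = np.argsort(d2[c], kind="stable")
        foreign = [int(labels[j]) for j in order if labels[j] != labels[c]]
        adj.append(sorted(set(foreign[:m_neighbors])))
    return adj


def make_planted_language(
    chart: ChipChart, spec: PlantedLanguageSpec
) -> tuple[Partition, LanguageNamingData]:
    """Ground-truth partition plus per-speaker responses with boundary confusion."""
    if spec.k_terms > len(chart):
        raise ValueError(f"k_terms={spec.k_terms} exceeds chart size {len(chart)}")
    planted = _planted_partition(chart, spec.k_terms, spec.seed)
    labels = planted.label_array()
    terms = np.array([f"t{lab}" for lab in labels])
    adjacency = _adjacent_categories(chart, labels)

    rng = np.random.default_rng(spec.seed + 1)
    speakers = []
    for sid in range(spec.n_speakers):
        responses = {}
        slips = rng.random(len(chart)) < spec.confusion_rate
        for c in range(len(chart)):
            if slips[c] and adjacency[c]:
                responses[c] = f"t{rng.choice(adjacency[c])}"
            else:
                responses[c] = terms[c]
        speakers.append(SpeakerResponses(language_id=0, speaker_id=sid, responses=responses))

    inventory = {f"t{lab}" for lab in np.unique(labels)}
    lang = LanguageNamingData(language_id=0, speakers=speakers, term_inventory=inventory)
    return planted, lang
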