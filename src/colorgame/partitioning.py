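"""Partitions of the chip chart ("mode maps") and simple baselines.

A :class:`Partition` assigns every chip of a chart exactly one category label.
Labels are opaque: all comparisons downstream go through label-invariant
measures (adjusted Rand index) or set structure, so word indices, survey terms
and cluster ids can be mixed freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np
import pandas as pd

from .color_domain import ChipChart

__all__ = ["Partition", "agent_partition", "random_partition", "term_count"]


@dataclass(frozen=True)
class Partition:
    """Total assignment of chip ids to category labels on a named chart."""

    labels: Mapping[int, Hashable]
    chart_ref: str = "chart"
    n_chips: int | None = None

    def __post_init__(self) -> None:
        n = self.n_chips if self.n_chips is not None else len(self.labels)
        missing = [i for i in range(n) if i not in self.labels]
        if missing or len(self.labels) != n:
            raise ValueError(
                f"partition must label chips 0..{n - 1} exactly once "
                f"(missing {missing[:5]}{'...' if len(missing) > 5 else ''})"
            )
        object.__setattr__(self, "labels", dict(self.labels))
        object.__setattr__(self, "n_chips", n)

    @property
    def term_count(self) -> int:
        return len(set(self.labels.values()))

    def label_array(self) -> np.ndarray:
        """Labels as an array indexed by chip id, factorized to integers."""
        raw = [self.labels[i] for i in range(self.n_chips)]
        codes, _ = pd.factorize(np.asarray(raw, dtype=object))
        return codes

    def groups(self) -> dict[Hashable, list[int]]:
        out: dict[Hashable, list[int]] = {}
        for i in range(self.n_chips):
            out.setdefault(self.labels[i], []).append(i)
        return out

    @classmethod
    def from_array(cls, labels: np.ndarray | list, chart_ref: str = "chart") -> "Partition":
        return cls(labels={i: lab for i, lab in enumerate(labels)}, chart_ref=chart_ref)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"chip_id": range(self.n_chips), "label": [self.labels[i] for i in range(self.n_chips)]}
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, chart_ref: str = "chart") -> "Partition":
        df = pd.read_csv(path, sep="\t")
        return cls(
            labels={int(r.chip_id): r.label for r in df.itertuples()}, chart_ref=chart_ref
        )


def agent_partition(params, chart: ChipChart) -> Partition:
    """Mode map of a sender agent: noise-free argmax word index for every chip."""
    from .agents import categorize_chart

    return Partition.from_array(categorize_chart(params, chart), chart_ref=chart.name)


def random_partition(chart: ChipChart, k: int, rng: np.random.Generator) -> Partition:
    """Uniform random partition into k groups with sizes differing by at most 1."""
    n = len(chart)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=int)
    for g, block in enumerate(np.array_split(perm, k)):
        labels[block] = g
    return Partition.from_array(labels, chart_ref=chart.name)


def term_count(p: Partition) -> int:
    """Number of distinct labels actually used."""
    return p.term_count
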