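"""Communication-cost and partition-quality measures.

Two routes to the communication cost of a naming system, both in bits under a
uniform need probability:

* **Expected surprise** starts from a probabilistic naming model ``p(w|c)``
  (survey fractions, or the trained sender's softmax) and a Bayes decoder
  ``p(c|w) = p(w|c) p(c) / sum_c' p(w|c') p(c')``; the cost at chip ``c`` is
  ``-sum_w p(w|c) log2 p(c|w)``.
* **KL loss** starts from a hard partition and an exemplar-based listener:
  ``p(c|w) = sum_{j in Cat(c)} sim(c, j) / sum_i sum_{j in Cat(i)} sim(i, j)``
  and the cost at ``c`` is ``-log2 p(c|w)``.

When the naming model is the deterministic indicator of a partition the two
coincide.  Well-formedness is the correlation-clustering objective of the
partition, and partitions are compared with the adjusted Rand index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .color_domain import ChipChart, SimilarityParams, similarity_matrix
from .partitioning import Partition

__all__ = [
    "NamingModel",
    "MetricReport",
    "AriSummary",
    "bayes_decoder",
    "exemplar_decoder",
    "expected_surprise",
    "aggregate_expected_surprise",
    "kl_loss_from_partition",
    "wellformedness",
    "adjusted_rand_index",
    "mean_pairwise_ari",
    "report",
]


@dataclass(frozen=True)
class NamingModel:
    """Per-chip distributions over terms, ``p(w | c)``."""

    p_w_given_c: Mapping[int, Mapping[Hashable, float]]

    def __post_init__(self) -> None:
        if not self.p_w_given_c:
            raise ValueError("naming model must cover at least one chip")
        for c, dist in self.p_w_given_c.items():
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"p(w|c) for chip {c} sums to {total}, not 1")

    @property
    def chips(self) -> list[int]:
        return sorted(self.p_w_given_c)

    @property
    def terms(self) -> list[Hashable]:
        out = set()
        for dist in self.p_w_given_c.values():
            out.update(w for w, p in dist.items() if p > 0)
        return sorted(out, key=str)

    @classmethod
    def from_partition(cls, part: Partition) -> "NamingModel":
        """Deterministic indicator model: each chip names its own category."""
        return cls({c: {lab: 1.0} for c, lab in part.labels.items()})

    @classmethod
    def from_agent(cls, params, chart: ChipChart) -> "NamingModel":
        """Query a trained sender with no environmental noise; terms are word indices."""
        from .agents import sender_word_probs

        w = sender_word_probs(params, chart.coords)
        return cls(
            {c: {int(i): float(p) for i, p in enumerate(row) if p > 0}
             for c, row in enumerate(w)}
        )


@dataclass(frozen=True)
class MetricReport:
    """Efficiency scores of one partition / naming system."""

    expected_surprise: float
    kl_loss: float
    wellformedness: float
    term_count: int


@dataclass(frozen=True)
class AriSummary:
    """Mean pairwise adjusted Rand index with a normal-approximation 95% CI."""

    mean: float
    ci_halfwidth: float
    n_pairs: int
    ci_defined: bool = True


def bayes_decoder(
    model: NamingModel, prior: Mapping[int, float] | None = None
) -> dict[Hashable, dict[int, float]]:
    """Posterior ``p(c | w)`` for every term with positive total mass.

    ``prior`` defaults to uniform over the model's chips and must sum to 1.
    """
    chips = model.chips
    if prior is None:
        prior = {c: 1.0 / len(chips) for c in chips}
    elif not np.isclose(sum(prior.values()), 1.0, atol=1e-9):
        raise ValueError("prior must sum to 1")
    joint: dict[Hashable, dict[int, float]] = {}
    for c in chips:
        for w, p in model.p_w_given_c[c].items():
            if p > 0:
                joint.setdefault(w, {})[c] = p * prior[c]
    decoder = {}
    for w, mass in joint.items():
        z = sum(mass.values())
        if z > 0:
            decoder[w] = {c: m / z for c, m in mass.items()}
    return decoder


def expected_surprise(
    model: NamingModel,
    decoder: Mapping[Hashable, Mapping[int, float]],
    chip: int,
) -> float:
    """Listener's expected surprise at one chip: ``-sum_w p(w|c) log2 p(c|w)``.

    A used term whose decoder puts zero mass on the chip yields ``inf`` with a
    warning (possible with sparse empirical models), never a silent drop.
    """
    total = 0.0
    for w, pw in model.p_w_given_c[chip].items():
        if pw == 0:
            continue
        pc = decoder.get(w, {}).get(chip, 0.0)
        if pc == 0.0:
            warnings.warn(
                f"decoder assigns zero mass to chip {chip} under term {w!r}; "
                "expected surprise is infinite",
                RuntimeWarning,
                stacklevel=2,
            )
            return float("inf")
        total -= pw * np.log2(pc)
    return total


def aggregate_expected_surprise(
    model: NamingModel, prior: Mapping[int, float] | None = None
) -> float:
    """Need-weighted average surprise over all chips (uniform need by default)."""
    chips = model.chips
    if prior is None:
        prior = {c: 1.0 / len(chips) for c in chips}
    decoder = bayes_decoder(model, prior)
    return float(sum(prior[c] * expected_surprise(model, decoder, c) for c in chips))


def _category_mass(labels: np.ndarray, sim: np.ndarray) -> np.ndarray:
    """mass[i, g] = total similarity of chip i to the chips of category g."""
    k = int(labels.max()) + 1
    member = np.zeros((len(labels), k))
    member[np.arange(len(labels)), labels] = 1.0
    return sim @ member


def exemplar_decoder(
    part: Partition, chart: ChipChart, simp: SimilarityParams = SimilarityParams()
) -> dict[Hashable, dict[int, float]]:
    """Exemplar listener of a partition: ``p(c|w)`` proportional, over all
    chips ``c`` of the universe, to c's similarity mass to word w's category.

    Each word's distribution sums to 1 over the whole chart, so it can be used
    wherever a Bayes decoder is expected.
    """
    labels = part.label_array()
    mass = _category_mass(labels, similarity_matrix(chart, simp))
    col = mass.sum(axis=0)
    inv_labels = {}
    for chip_id in range(part.n_chips):
        inv_labels[part.labels[chip_id]] = labels[chip_id]
    return {
        word: {c: float(mass[c, g] / col[g]) for c in range(part.n_chips)}
        for word, g in inv_labels.items()
    }


def kl_loss_from_partition(
    part: Partition,
    chart: ChipChart,
    simp: SimilarityParams = SimilarityParams(),
    per_category_norm: bool = False,
) -> float:
    """Communication cost in bits of a mode map via the exemplar listener.

    For each chip ``c`` the listener hears the word of c's category and
    reconstructs ``p(c|w) = sum_{j in Cat(c)} sim(c, j) /
    sum_{i in U} sum_{j in Cat(c)} sim(i, j)`` — c's similarity mass to its
    category, normalized over the whole universe, so each word's
    reconstruction distribution sums to 1 across the chart.  The cost is the
    uniform-need average of ``-log2 p(c|w)``.  ``per_category_norm`` switches
    to renormalizing within the category instead (non-default variant).
    """
    labels = part.label_array()
    sim = similarity_matrix(chart, simp)
    mass = _category_mass(labels, sim)
    num = mass[np.arange(len(labels)), labels]
    if per_category_norm:
        member_mass = np.array([num[labels == labels[c]].sum() for c in range(len(labels))])
        denom = member_mass
    else:
        denom = mass.sum(axis=0)[labels]
    return float(np.mean(-np.log2(num / denom)))


def wellformedness(
    part: Partition, chart: ChipChart, simp: SimilarityParams = SimilarityParams()
) -> float:
    """Sum of ``sim - 1/2`` over unordered within-category chip pairs."""
    labels = part.label_array()
    sim = similarity_matrix(chart, simp)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    return float(np.sum((sim - 0.5) * same) / 2.0)


def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Chance-corrected, label-permutation-invariant partition similarity."""
    if p1.chart_ref != p2.chart_ref or p1.n_chips != p2.n_chips:
        raise ValueError("partitions must be defined on the same chart")
    return float(adjusted_rand_score(p1.label_array(), p2.label_array()))


def mean_pairwise_ari(
    group1: Sequence[Partition], group2: Sequence[Partition] | None = None
) -> AriSummary:
    """Mean ARI over all cross-group pairs, or within-group unordered pairs.

    The CI halfwidth is ``1.96 * sd / sqrt(n_pairs)``; with a single pair the
    CI is undefined and reported as 0 with ``ci_defined=False``.
    """
    if not group1 or (group2 is not None and not group2):
        raise ValueError("groups must be non-empty")
    if group2 is None:
        if len(group1) < 2:
            raise ValueError("within-group mode needs at least two partitions")
        scores = [
            adjusted_rand_index(group1[i], group1[j])
            for i in range(len(group1))
            for j in range(i + 1, len(group1))
        ]
    else:
        scores = [adjusted_rand_index(a, b) for a in group1 for b in group2]
    scores = np.asarray(scores)
    n = len(scores)
    if n == 1:
        return AriSummary(float(scores[0]), 0.0, 1, ci_defined=False)
    ci = 1.96 * float(np.std(scores, ddof=1)) / np.sqrt(n)
    return AriSummary(float(scores.mean()), ci, n)


def report(
    part: Partition, chart: ChipChart, simp: SimilarityParams = SimilarityParams()
) -> MetricReport:
    """Full efficiency report for one partition (deterministic naming model)."""
    model = NamingModel.from_partition(part)
    return MetricReport(
        expected_surprise=aggregate_expected_surprise(model),
        kl_loss=kl_loss_from_partition(part, chart, simp),
        wellformedness=wellformedness(part, chart, simp),
        term_count=part.term_count,
    )
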