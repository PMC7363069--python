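"""Training loops for the color game.

One *episode* is one batch update.  In every game of a batch a target chip is
drawn uniformly from the chart, the sender observes its CIELAB coordinates
perturbed by environmental noise (variance ``sigma_e_sq`` per component) and
emits a word vector, the message crosses the channel, and the receiver's
softmax over the chart is sampled for a guess.  The reward is the CIELAB
similarity between the guess and the *clean* target chip.

Two REINFORCE variants are provided:

* ``continuous`` — the message is the sender's word-probability vector plus
  Gaussian channel noise (variance ``sigma_c_sq``).  The channel is
  differentiable, so a single score-function loss
  ``J = -(1/Nb) * sum_n log p(c_n | t_n) * r_n`` trains both agents end to end.
* ``discrete`` — a one-hot message is sampled from the sender softmax.  No
  gradient crosses the channel; sender and receiver each get their own loss
  with a running-mean reward baseline ``B`` for variance reduction:
  ``J_s = -(1/Nb) * sum_n log p(m_n | t_n) * (r_n - B_n)`` and analogously for
  the receiver.

All gradients are derived by hand and applied with an ADAM optimizer
(lr 0.001, beta1 0.9, beta2 0.999, eps 1e-8 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import (
    AgentParameters,
    init_agent_parameters,
    relu,
    softmax,
)
from .color_domain import ChipChart, SimilarityParams, similarity_matrix

__all__ = [
    "GameConfig",
    "TrainingTrace",
    "TrainingDivergedError",
    "AdamOptimizer",
    "reward",
    "play_batch_continuous",
    "play_batch_discrete",
    "train",
]

LOG_FLOOR = 1e-12  # log-probabilities are clipped below at log(LOG_FLOOR)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the episode index."""

    def __init__(self, episode: int):
        self.episode = episode
        super().__init__(f"training diverged (non-finite loss) at episode {episode}")


@dataclass
class GameConfig:
    """Hyperparameters of one training run.

    ``batch_size`` / ``n_episodes`` default to the standard settings of each
    message mode: continuous 100 x 20000, discrete 256 x 25000.

    Noise parameters are variances (per component).  The default channel
    noise corresponds to a noise scale of 0.1 on the message vector, i.e.
    variance 0.01; at an order of magnitude more channel noise the receiver
    learns to null out unused message dimensions and the vocabulary pins at
    2-4 words for every environmental-noise level, losing the noise-vocabulary
    trade-off the game is built to study (see the methods note).
    """

    sigma_e_sq: float = 1.0
    sigma_c_sq: float = 0.01
    message_mode: str = "continuous"
    batch_size: int | None = None
    n_episodes: int | None = None
    learning_rate: float = 0.001
    seed: int = 0
    hidden_width: int = 20
    message_dim: int = 50
    scale_c: float = 0.001
    init_scale: float = 0.1
    kl_probe_interval: int | None = 100
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.message_mode not in ("continuous", "discrete"):
            raise ValueError(f"unknown message_mode {self.message_mode!r}")
        if self.batch_size is None:
            self.batch_size = 100 if self.message_mode == "continuous" else 256
        if self.n_episodes is None:
            self.n_episodes = 20000 if self.message_mode == "continuous" else 25000
        if self.sigma_e_sq < 0 or self.sigma_c_sq < 0:
            raise ValueError("noise variances must be nonnegative")

    @property
    def similarity_params(self) -> SimilarityParams:
        return SimilarityParams(scale_c=self.scale_c)


@dataclass
class TrainingTrace:
    """Per-episode record of a training run.

    ``kl_probe`` holds ``(episode, kl_bits)`` pairs at the probe interval;
    ``snapshots`` holds ``(episode, term_count, labels)`` captured whenever the
    noise-free mode map changes its number of words.
    """

    mean_reward: list[float] = field(default_factory=list)
    baseline: list[float] = field(default_factory=list)
    term_count: list[int] = field(default_factory=list)
    kl_probe: list[tuple[int, float]] = field(default_factory=list)
    snapshots: list[tuple[int, int, np.ndarray]] = field(default_factory=list)

    @property
    def n_episodes(self) -> int:
        return len(self.mean_reward)


def reward(
    guess: int, target: int, chart: ChipChart, p: SimilarityParams = SimilarityParams()
) -> float:
    """Similarity between the guessed and the true target chip, in (0, 1]."""
    n = len(chart)
    if not (0 <= guess < n and 0 <= target < n):
        raise ValueError(f"chip ids must be in [0, {n}), got guess={guess} target={target}")
    d2 = float(np.sum((chart.coords[guess] - chart.coords[target]) ** 2))
    return float(np.exp(-p.scale_c * d2))


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a probability matrix."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0  # guard against rounding
    return np.minimum((cum < u[:, None]).sum(axis=1), probs.shape[1] - 1)


def _clipped_log(p: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(p, LOG_FLOOR))


def play_batch_continuous(
    params: AgentParameters,
    chart: ChipChart,
    cfg: GameConfig,
    rng: np.random.Generator,
) -> tuple[float, dict[str, np.ndarray], dict]:
    """One batch of games with a differentiable channel.

    Returns the REINFORCE loss, the gradient of the loss with respect to every
    parameter array, and a trace row with the batch mean reward.
    """
    nb = cfg.batch_size
    coords = chart.coords
    targets = rng.integers(0, len(chart), size=nb)

    x = coords[targets]
    if cfg.sigma_e_sq > 0:
        x = x + rng.normal(0.0, np.sqrt(cfg.sigma_e_sq), size=x.shape)

    hs_pre = x @ params.theta_s + params.b_s1
    hs = relu(hs_pre)
    w = softmax(hs @ params.phi_s + params.b_s2)

    m = w
    if cfg.sigma_c_sq > 0:
        m = w + rng.normal(0.0, np.sqrt(cfg.sigma_c_sq), size=w.shape)

    hr_pre = m @ params.theta_r + params.b_r1
    hr = relu(hr_pre)
    p = softmax(hr @ params.phi_r + params.b_r2)

    guesses = _sample_rows(p, rng)
    sq = np.sum((coords[guesses] - coords[targets]) ** 2, axis=1)
    r = np.exp(-cfg.scale_c * sq)

    p_guess = p[np.arange(nb), guesses]
    loss = float(-np.mean(_clipped_log(p_guess) * r))

    # d(-log p[c] * r / Nb) / dz_r = (p - onehot(c)) * r / Nb; rows at the log
    # floor contribute a constant to the loss and therefore zero gradient.
    scale = np.where(p_guess > LOG_FLOOR, r, 0.0) / nb
    g = p.copy()
    g[np.arange(nb), guesses] -= 1.0
    g *= scale[:, None]

    grads: dict[str, np.ndarray] = {}
    grads["phi_r"] = hr.T @ g
    grads["b_r2"] = g.sum(axis=0)
    dhr = (g @ params.phi_r.T) * (hr_pre > 0)
    grads["theta_r"] = m.T @ dhr
    grads["b_r1"] = dhr.sum(axis=0)

    dw = dhr @ params.theta_r.T  # channel noise is additive: dm = dw
    dzs = w * (dw - np.sum(dw * w, axis=1, keepdims=True))
    grads["phi_s"] = hs.T @ dzs
    grads["b_s2"] = dzs.sum(axis=0)
    dhs = (dzs @ params.phi_s.T) * (hs_pre > 0)
    grads["theta_s"] = x.T @ dhs
    grads["b_s1"] = dhs.sum(axis=0)

    return loss, grads, {"mean_reward": float(r.mean())}


def play_batch_discrete(
    params: AgentParameters,
    chart: ChipChart,
    cfg: GameConfig,
    rng: np.random.Generator,
    baseline_count: int = 0,
    baseline_sum: float = 0.0,
) -> tuple[float, float, dict[str, np.ndarray], dict]:
    """One batch of games with sampled one-hot messages.

    The baseline ``B_n`` for game ``n`` is the running mean of every reward
    observed before it (across the whole run), 0 before the first reward.
    Returns (sender loss, receiver loss, gradients, trace row); the trace row
    carries the updated baseline state.
    """
    nb = cfg.batch_size
    coords = chart.coords
    targets = rng.integers(0, len(chart), size=nb)

    x = coords[targets]
    if cfg.sigma_e_sq > 0:
        x = x + rng.normal(0.0, np.sqrt(cfg.sigma_e_sq), size=x.shape)

    hs_pre = x @ params.theta_s + params.b_s1
    hs = relu(hs_pre)
    w = softmax(hs @ params.phi_s + params.b_s2)
    msg_idx = _sample_rows(w, rng)
    m = np.zeros_like(w)
    m[np.arange(nb), msg_idx] = 1.0

    hr_pre = m @ params.theta_r + params.b_r1
    hr = relu(hr_pre)
    p = softmax(hr @ params.phi_r + params.b_r2)
    guesses = _sample_rows(p, rng)

    sq = np.sum((coords[guesses] - coords[targets]) ** 2, axis=1)
    r = np.exp(-cfg.scale_c * sq)

    prior = np.concatenate(([0.0], np.cumsum(r[:-1]))) + baseline_sum
    counts = baseline_count + np.arange(nb)
    b = np.divide(prior, counts, out=np.zeros(nb), where=counts > 0)
    adv = r - b

    w_msg = w[np.arange(nb), msg_idx]
    p_guess = p[np.arange(nb), guesses]
    sender_loss = float(-np.mean(_clipped_log(w_msg) * adv))
    receiver_loss = float(-np.mean(_clipped_log(p_guess) * adv))

    grads: dict[str, np.ndarray] = {}

    gs = w.copy()
    gs[np.arange(nb), msg_idx] -= 1.0
    gs *= (np.where(w_msg > LOG_FLOOR, adv, 0.0) / nb)[:, None]
    grads["phi_s"] = hs.T @ gs
    grads["b_s2"] = gs.sum(axis=0)
    dhs = (gs @ params.phi_s.T) * (hs_pre > 0)
    grads["theta_s"] = x.T @ dhs
    grads["b_s1"] = dhs.sum(axis=0)

    gr = p.copy()
    gr[np.arange(nb), guesses] -= 1.0
    gr *= (np.where(p_guess > LOG_FLOOR, adv, 0.0) / nb)[:, None]
    grads["phi_r"] = hr.T @ gr
    grads["b_r2"] = gr.sum(axis=0)
    dhr = (gr @ params.phi_r.T) * (hr_pre > 0)
    grads["theta_r"] = m.T @ dhr
    grads["b_r1"] = dhr.sum(axis=0)

    row = {
        "mean_reward": float(r.mean()),
        "baseline_count": baseline_count + nb,
        "baseline_sum": baseline_sum + float(r.sum()),
    }
    return sender_loss, receiver_loss, grads, row


class AdamOptimizer:
    """Plain ADAM over a dict of parameter arrays."""

    def __init__(self, shapes: dict[str, tuple], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _kl_from_labels(labels: np.ndarray, sim: np.ndarray) -> float:
    """Communication cost in bits of a mode map, from a precomputed similarity matrix.

    Exemplar listener: ``p(c|w)`` is chip ``c``'s similarity mass to its own
    category, normalized over every chip's mass to that same category.
    """
    k = int(labels.max()) + 1
    member = np.zeros((len(labels), k))
    member[np.arange(len(labels)), labels] = 1.0
    mass = sim @ member  # mass[i, g] = total similarity of chip i to category g
    num = mass[np.arange(len(labels)), labels]
    denom = mass.sum(axis=0)[labels]
    return float(np.mean(-np.log2(num / denom)))


def train(
    chart: ChipChart, cfg: GameConfig
) -> tuple[AgentParameters, TrainingTrace]:
    """Train a sender/receiver pair on a chart; deterministic under ``cfg.seed``.

    Records the batch mean reward, the running baseline, and the noise-free
    term count every episode; probes the KL loss of the current mode map every
    ``kl_probe_interval`` episodes; and snapshots the mode map whenever its
    term count changes.  Raises :class:`TrainingDivergedError` on a non-finite
    loss.
    """
    from .agents import categorize_chart

    rng = np.random.default_rng(cfg.seed)
    params = init_agent_parameters(
        len(chart), rng, hidden_width=cfg.hidden_width,
        message_dim=cfg.message_dim, init_scale=cfg.init_scale,
    )
    arrays = params.arrays()
    opt = AdamOptimizer(
        {k: v.shape for k, v in arrays.items()}, lr=cfg.learning_rate,
        beta1=cfg.adam_beta1, beta2=cfg.adam_beta2, eps=cfg.adam_eps,
    )
    trace = TrainingTrace()
    sim = similarity_matrix(chart, cfg.similarity_params) if cfg.kl_probe_interval else None

    b_count, b_sum = 0, 0.0
    last_terms: int | None = None
    for episode in range(cfg.n_episodes):
        if cfg.message_mode == "continuous":
            loss, grads, row = play_batch_continuous(params, chart, cfg, rng)
            losses = (loss,)
        else:
            s_loss, r_loss, grads, row = play_batch_discrete(
                params, chart, cfg, rng, b_count, b_sum
            )
            b_count, b_sum = row["baseline_count"], row["baseline_sum"]
            losses = (s_loss, r_loss)
        if not all(np.isfinite(losses)):
            raise TrainingDivergedError(episode)
        opt.step(arrays, grads)

        labels = categorize_chart(params, chart)
        terms = int(len(np.unique(labels)))
        trace.mean_reward.append(row["mean_reward"])
        trace.baseline.append(b_sum / b_count if b_count else 0.0)
        trace.term_count.append(terms)
        if terms != last_terms:
            trace.snapshots.append((episode, terms, labels.copy()))
            last_terms = terms
        if sim is not None and (
            episode % cfg.kl_probe_interval == 0 or episode == cfg.n_episodes - 1
        ):
            trace.kl_probe.append((episode, _kl_from_labels(labels, sim)))

    return params, trace
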