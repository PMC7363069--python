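"""Sender and receiver policies: one-hidden-layer perceptrons with softmax output.

The sender maps a (possibly noise-perturbed) CIELAB coordinate to a
distribution over ``d`` message slots ("words"):

    w = softmax(phi_s^T relu(theta_s^T x + b))      x in R^3

The receiver maps a message vector to a distribution over the chart:

    p(U | m) = softmax(phi_r^T relu(theta_r^T m + b))

Both nets use ``k = 20`` hidden units and ``d = 50`` message dimensions by
default; ``d`` caps the number of color terms the pair can ever use.  Weights
are stored in (input, output) orientation, so the forward pass is
``x @ theta + bias``.  Implemented directly in NumPy; the training module
provides the matching hand-derived gradients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .color_domain import ChipChart, ColorChip

__all__ = [
    "AgentParameters",
    "Message",
    "init_agent_parameters",
    "softmax",
    "relu",
    "sender_forward",
    "sender_word_probs",
    "channel_noise",
    "receiver_forward",
    "categorize",
    "categorize_chart",
]

DEFAULT_HIDDEN = 20
DEFAULT_MESSAGE_DIM = 50
INIT_SCALE = 0.1  # weights ~ Uniform[-0.1, 0.1]; biases zero


@dataclass
class AgentParameters:
    """Weights of the sender and receiver MLPs.

    theta_s: (3, k)   sender input->hidden
    phi_s:   (k, d)   sender hidden->word logits
    theta_r: (d, k)   receiver message->hidden
    phi_r:   (k, n)   receiver hidden->chip logits, n = chart size
    """

    theta_s: np.ndarray
    phi_s: np.ndarray
    theta_r: np.ndarray
    phi_r: np.ndarray
    b_s1: np.ndarray
    b_s2: np.ndarray
    b_r1: np.ndarray
    b_r2: np.ndarray

    def __post_init__(self) -> None:
        k = self.theta_s.shape[1]
        d = self.phi_s.shape[1]
        n = self.phi_r.shape[1]
        expected = {
            "theta_s": (3, k),
            "phi_s": (k, d),
            "theta_r": (d, k),
            "phi_r": (k, n),
            "b_s1": (k,),
            "b_s2": (d,),
            "b_r1": (k,),
            "b_r2": (n,),
        }
        for name, shape in expected.items():
            got = getattr(self, name).shape
            if got != shape:
                raise ValueError(f"inconsistent agent shapes: {name} is {got}, expected {shape}")

    @property
    def hidden_width(self) -> int:
        return self.theta_s.shape[1]

    @property
    def message_dim(self) -> int:
        return self.phi_s.shape[1]

    @property
    def universe_size(self) -> int:
        return self.phi_r.shape[1]

    def arrays(self) -> dict[str, np.ndarray]:
        return {
            "theta_s": self.theta_s, "phi_s": self.phi_s,
            "theta_r": self.theta_r, "phi_r": self.phi_r,
            "b_s1": self.b_s1, "b_s2": self.b_s2,
            "b_r1": self.b_r1, "b_r2": self.b_r2,
        }

    def copy(self) -> "AgentParameters":
        return AgentParameters(**{k: v.copy() for k, v in self.arrays().items()})

    def save(self, path: str | Path, meta: dict | None = None) -> None:
        """Write a portable JSON checkpoint of all matrices plus metadata."""
        payload = {k: v.tolist() for k, v in self.arrays().items()}
        payload["_meta"] = {
            "k": self.hidden_width, "d": self.message_dim, "n": self.universe_size,
            **(meta or {}),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "AgentParameters":
        payload = json.loads(Path(path).read_text())
        payload.pop("_meta", None)
        return cls(**{k: np.asarray(v, dtype=float) for k, v in payload.items()})


@dataclass(frozen=True)
class Message:
    """A d-dimensional message: a word-probability vector, or a one-hot draw."""

    values: np.ndarray
    discrete: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.discrete:
            if not (np.count_nonzero(v) == 1 and np.isclose(v.max(), 1.0)):
                raise ValueError("discrete message must be one-hot")
        else:
            if np.any(v < -1e-12) or not np.isclose(v.sum(), 1.0, atol=1e-9):
                raise ValueError("continuous message must be a probability vector")


def init_agent_parameters(
    universe_size: int,
    rng: np.random.Generator,
    hidden_width: int = DEFAULT_HIDDEN,
    message_dim: int = DEFAULT_MESSAGE_DIM,
    init_scale: float = INIT_SCALE,
) -> AgentParameters:
    """Random initialization: weights Uniform[-init_scale, init_scale], biases zero."""
    k, d, n = hidden_width, message_dim, universe_size
    u = lambda *shape: rng.uniform(-init_scale, init_scale, size=shape)
    return AgentParameters(
        theta_s=u(3, k), phi_s=u(k, d), theta_r=u(d, k), phi_r=u(k, n),
        b_s1=np.zeros(k), b_s2=np.zeros(d), b_r1=np.zeros(k), b_r2=np.zeros(n),
    )


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def relu(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0)


def sender_word_probs(params: AgentParameters, noisy_coords: np.ndarray) -> np.ndarray:
    """Sender softmax over words for one coordinate vector or a batch of them."""
    x = np.asarray(noisy_coords, dtype=float)
    h = relu(x @ params.theta_s + params.b_s1)
    return softmax(h @ params.phi_s + params.b_s2)


def sender_forward(
    params: AgentParameters,
    noisy_coords: np.ndarray,
    sim_mode: str = "continuous",
    rng: np.random.Generator | None = None,
) -> Message:
    """Run the sender on a single (noisy) coordinate vector.

    ``continuous`` returns the word-probability vector itself; ``discrete_sample``
    samples a one-hot message from it (requires ``rng``).
    """
    w = sender_word_probs(params, noisy_coords)
    if w.ndim != 1:
        raise ValueError("sender_forward takes a single 3-vector; use sender_word_probs for batches")
    if sim_mode == "continuous":
        return Message(values=w, discrete=False)
    if sim_mode == "discrete_sample":
        if rng is None:
            raise ValueError("discrete_sample mode requires an rng")
        idx = rng.choice(len(w), p=w)
        one_hot = np.zeros_like(w)
        one_hot[idx] = 1.0
        return Message(values=one_hot, discrete=True)
    raise ValueError(f"unknown sim_mode {sim_mode!r}")


def channel_noise(
    msg: Message, sigma_c_sq: float, rng: np.random.Generator
) -> np.ndarray:
    """Message plus iid Gaussian noise of variance ``sigma_c_sq`` per component.

    Discrete messages pass through unchanged: at evaluation time the one-hot
    vector is the symbol itself and the channel is treated as noiseless.
    """
    if sigma_c_sq < 0:
        raise ValueError(f"noise variance must be nonnegative, got {sigma_c_sq}")
    v = msg.values
    if msg.discrete or sigma_c_sq == 0:
        return v.copy()
    return v + rng.normal(0.0, np.sqrt(sigma_c_sq), size=v.shape)


def receiver_forward(params: AgentParameters, m: np.ndarray) -> np.ndarray:
    """Receiver softmax over all chips given a message vector (or batch)."""
    m = np.asarray(m, dtype=float)
    if m.shape[-1] != params.message_dim:
        raise ValueError(
            f"message has dimension {m.shape[-1]}, agent expects {params.message_dim}"
        )
    h = relu(m @ params.theta_r + params.b_r1)
    return softmax(h @ params.phi_r + params.b_r2)


def categorize(params: AgentParameters, chip: ColorChip) -> int:
    """Word index the sender assigns to a chip with no environmental noise.

    Argmax of the sender word vector; ties resolve to the smallest index.
    """
    w = sender_word_probs(params, np.asarray(chip.coords))
    return int(np.argmax(w))


def categorize_chart(params: AgentParameters, chart: ChipChart) -> np.ndarray:
    """Vectorized ``categorize`` over every chip of the chart."""
    w = sender_word_probs(params, chart.coords)
    return np.argmax(w, axis=1)
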