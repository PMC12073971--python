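"""GO-level feed-forward network with hierarchy-derived initialization.

The network has one layer per GO hierarchy level occurring in the union of a
direct and an indirect term cluster.  Each layer carries a scalar input x
(mean normalized COEs of the genes annotated to the layer's terms), a weight
w and a bias b derived from the hierarchy:

    b_l = (#terms at level l) / (total #terms across both clusters)
    w_l = (mean GO level of the layer's terms) / (max level present)

A forward pass collapses the layers into one pre-activation
s = sum_l (w_l x_l + b_l) followed by a logistic sigmoid, y = 1/(1+e^-s).
Training minimizes the squared-Euclidean loss E = 1/2 ||y_d - y_p||^2 with a
bespoke, gradient-free weight update applied per layer:

    w_new = sigmoid(x * w) + s * ||y_d - y_p||

(the shared pre-activation s and the error norm modulate a squashed version
of each layer's own contribution).  The scheme has no randomness; training
is fully deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

from scipy.special import expit

from .clustering import TermCluster


@dataclass(frozen=True)
class LayerSpec:
    """One level-layer: its GO level, member terms with origin, and x/w/b."""

    go_level: int
    terms: tuple[tuple[str, str], ...]  # (GO id, "direct" | "indirect")
    x: float
    w: float
    b: float

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a layer needs at least one member term")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"bias must lie in [0, 1], got {self.b}")


@dataclass
class EpochRecord:
    epoch: int
    s: float
    y_predicted: float
    e: float
    weights: tuple[float, ...]


@dataclass
class TrainState:
    history: list[EpochRecord]
    stop_reason: Literal["tol_reached", "max_epochs", "loss_stalled"]

    @property
    def final(self) -> EpochRecord:
        return self.history[-1]


@dataclass
class FnnNetwork:
    """Ordered layers (ascending GO level) plus the last forward-pass state."""

    layers: list[LayerSpec]
    s: float | None = None
    y_predicted: float | None = None
    y_desired: float | None = None
    e: float | None = None
    epoch: int = 0


@dataclass(frozen=True)
class Loss:
    """Squared-Euclidean loss E = 1/2 ||y_d - y_p||^2 and the plain distance."""

    e: float
    distance: float


def sigmoid(s: float) -> float:
    """Overflow-safe logistic function."""
    return float(expit(s))


def sigmoid_derivative(s: float) -> float:
    """d/ds sigmoid(s) = sigmoid(s) (1 - sigmoid(s)); always in (0, 0.25]."""
    if not math.isfinite(s):
        raise ValueError("s must be finite")
    # exp(-|s|)/(1+exp(-|s|))^2 is symmetric and keeps positivity down to
    # the exp underflow (|s| ~ 745), unlike the naive expit(s)*(1-expit(s)).
    t = math.exp(-abs(s))
    return t / (1.0 + t) ** 2


def forward(layers: Sequence[LayerSpec]) -> tuple[float, float]:
    """Collapse the layers into (s, y): s = sum(w x + b), y = sigmoid(s)."""
    if not layers:
        raise ValueError("network has no layers")
    s = 0.0
    for layer in layers:
        contribution = layer.w * layer.x + layer.b
        if not math.isfinite(contribution):
            raise ValueError(f"non-finite contribution at level {layer.go_level}")
        s += contribution
    return s, sigmoid(s)


def loss(y_desired: float, y_predicted: float) -> Loss:
    distance = abs(y_desired - y_predicted)
    return Loss(e=0.5 * distance**2, distance=distance)


def update_weights(
    layers: Sequence[LayerSpec], s: float, y_desired: float, y_predicted: float
) -> list[LayerSpec]:
    """Apply the bespoke update w_new = sigmoid(x w) + s ||y_d - y_p|| per layer.

    Returns fresh layers; the originals are untouched.  With zero error the
    update reduces to w_new = sigmoid(x w) exactly.
    """
    err = abs(y_desired - y_predicted)
    out = []
    for layer in layers:
        w_new = float(expit(layer.x * layer.w)) + s * err
        if not math.isfinite(w_new):
            raise ValueError(f"weight update diverged at level {layer.go_level}")
        out.append(
            LayerSpec(go_level=layer.go_level, terms=layer.terms, x=layer.x,
                      w=w_new, b=layer.b)
        )
    return out


def build_layers(
    direct: TermCluster,
    indirect: TermCluster,
    levels: Mapping[str, int],
    coes: Mapping[str, float],
    annotations: Mapping[str, set[str] | Sequence[str]],
    weight_mode: Literal["normalized", "raw"] = "normalized",
) -> list[LayerSpec]:
    """Construct level-layers from a direct and an indirect cluster.

    One layer per GO level occurring among the two clusters' terms, in
    ascending order.  Biases are the per-level term counts normalized by the
    total term count (they sum to 1); weights are the layer's mean GO level,
    divided by the maximum level present unless ``weight_mode="raw"``; x is
    the mean normalized COEs score of the genes annotated to the layer's
    terms (0 with a warning when no gene touches the layer).
    """
    tagged = [(t, "direct") for t in direct.members] + [
        (t, "indirect") for t in indirect.members
    ]
    if not tagged:
        raise ValueError("both clusters are empty")
    missing = [t for t, _ in tagged if t not in levels]
    if missing:
        raise KeyError(f"terms without level assignment: {', '.join(sorted(missing))}")

    by_level: dict[int, list[tuple[str, str]]] = {}
    for term, origin in tagged:
        by_level.setdefault(levels[term], []).append((term, origin))
    total = len(tagged)
    max_level = max(by_level)

    term_genes: dict[str, list[str]] = {}
    for gene, terms in annotations.items():
        for term in terms:
            term_genes.setdefault(term, []).append(gene)

    layers = []
    for level in sorted(by_level):
        members = by_level[level]
        genes = sorted(
            {
                g
                for term, _ in members
                for g in term_genes.get(term, [])
                if g in coes
            }
        )
        x = sum(coes[g] for g in genes) / len(genes) if genes else 0.0
        mean_level = sum(levels[t] for t, _ in members) / len(members)
        w = mean_level / max_level if weight_mode == "normalized" else mean_level
        layers.append(
            LayerSpec(
                go_level=level,
                terms=tuple(members),
                x=x,
                w=w,
                b=len(members) / total,
            )
        )
    return layers


def train(
    network: FnnNetwork,
    y_desired: float,
    max_epochs: int = 1000,
    tol: float = 1e-4,
    stall_window: int = 5,
) -> TrainState:
    """Iterate forward pass / loss / weight update until convergence.

    Stops when the loss drops below ``tol`` (``tol_reached``), when it fails
    to decrease for ``stall_window`` consecutive epochs (``loss_stalled``),
    or after ``max_epochs`` updates.  Epoch 0 records the state before any
    update; the full trace is kept on the returned :class:`TrainState`.
    """
    if max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")

    def record(epoch: int) -> EpochRecord:
        s, y = forward(network.layers)
        e = loss(y_desired, y).e
        if not math.isfinite(e):
            raise ValueError(f"loss diverged at epoch {epoch}")
        network.s, network.y_predicted, network.e = s, y, e
        network.y_desired = y_desired
        network.epoch = epoch
        return EpochRecord(
            epoch=epoch, s=s, y_predicted=y, e=e,
            weights=tuple(layer.w for layer in network.layers),
        )

    history = [record(0)]
    if history[0].e < tol:
        return TrainState(history=history, stop_reason="tol_reached")

    stalled = 0
    for epoch in range(1, max_epochs + 1):
        network.layers = update_weights(
            network.layers, network.s, y_desired, network.y_predicted
        )
        history.append(record(epoch))
        if history[-1].e < tol:
            return TrainState(history=history, stop_reason="tol_reached")
        stalled = stalled + 1 if history[-1].e >= history[-2].e else 0
        if stalled >= stall_window:
            return TrainState(history=history, stop_reason="loss_stalled")
    return TrainState(history=history, stop_reason="max_epochs")
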