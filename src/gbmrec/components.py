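"""Differentiable building blocks for the balanced survival ensembles.

Three architectural pieces plus one penalty:

* LassoNet shared representation — a linear skip connection in parallel with
  a small MLP, trained under a hierarchical sparsity constraint: feature j
  may enter the nonlinear part only while its skip weight is active
  (``hier_prox`` enforces ||W1[:, j]||_inf <= M |theta_j| exactly).
* NODE risk heads — ensembles of oblivious decision trees: each tree picks
  one (soft) feature per depth level, compares it to a learned threshold
  through a sigmoid gate, and emits the expectation of its leaf responses
  under the product-of-gates leaf distribution.
* Plain MLP blocks for the comparator networks.
* ``ipm_penalty`` — squared maximum mean discrepancy (RBF kernel,
  V-statistic) between the representations of the two treatment groups; the
  integral-probability-metric regularizer that balances the shared
  representation.

All blocks run on the package's numpy autodiff; gradients are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

__all__ = ["LassoNetSpec", "NODESpec", "RepresentationBatch", "MLP", "LassoNet",
           "NODE", "lassonet_forward", "node_forward", "hier_prox", "ipm_penalty"]

_ACTIVATIONS = {"tanh": lambda t: t.tanh(), "relu": lambda t: t.relu(),
                "sigmoid": lambda t: t.sigmoid()}

_MAX_DEPTH = 10  # 2^depth leaves; deeper trees are a configuration error


@dataclass
class LassoNetSpec:
    in_features: int
    hidden: tuple = (16,)
    lambda_skip: float = 0.0
    M: float = 10.0
    activation: str = "tanh"

    def validate(self):
        if self.in_features < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("widths must be positive")
        if self.lambda_skip < 0 or self.M <= 0:
            raise ValueError("lambda_skip must be >= 0 and M > 0")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        return self


@dataclass
class NODESpec:
    in_features: int
    n_trees: int = 8
    depth: int = 3
    response_dim: int = 1
    n_layers: int = 1
    temperature: float = 1.0

    def validate(self):
        if self.n_trees < 1 or self.depth < 1 or self.n_layers < 1:
            raise ValueError("trees, depth and layers must be >= 1")
        if self.depth > _MAX_DEPTH:
            raise ValueError(f"depth {self.depth} exceeds the 2^{_MAX_DEPTH}-leaf cap")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        return self


@dataclass
class RepresentationBatch:
    """Latent representation with treatment labels, fed to the IPM penalty."""

    rep: object          # Tensor or ndarray, (n, d)
    treatment: np.ndarray  # (n,) in {0, 1}

    def __post_init__(self):
        self.treatment = np.asarray(self.treatment).ravel()
        n = self.rep.shape[0]
        if len(self.treatment) != n:
            raise ValueError("representation and treatment lengths differ")


# --------------------------------------------------------------------------
# modules
# --------------------------------------------------------------------------
class MLP:
    """Plain fully connected network; returns (last_hidden, output)."""

    def __init__(self, in_features, hidden, out_features=1, activation="tanh",
                 rng=None, init_scale=None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.activation = _ACTIVATIONS[activation]
        widths = [in_features, *hidden, out_features]
        self.layers = []
        for a, b in zip(widths[:-1], widths[1:]):
            s = init_scale if init_scale is not None else np.sqrt(1.0 / a)
            W = Tensor.param(rng.normal(0, s, (a, b)))
            c = Tensor.param(np.zeros((1, b)))
            self.layers.append((W, c))

    def parameters(self):
        return [p for pair in self.layers for p in pair]

    def forward(self, x: Tensor):
        h = x
        for W, c in self.layers[:-1]:
            h = self.activation(h @ W + c)
        W, c = self.layers[-1]
        return h, h @ W + c


class LassoNet:
    """Linear skip + MLP with the hierarchical sparsity parametrization.

    ``forward`` returns (representation, output): the output is
    skip(x) + MLP(x) (scalar per subject); the representation is the last
    hidden layer concatenated with the skip contribution, the surface on
    which the treatment-balancing penalty acts.
    """

    def __init__(self, spec: LassoNetSpec, rng=None):
        self.spec = spec.validate()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.theta = Tensor.param(rng.normal(0, 0.1, (spec.in_features, 1)))
        self.mlp = MLP(spec.in_features, spec.hidden, 1, spec.activation, rng)

    @property
    def rep_dim(self):
        return self.spec.hidden[-1] + 1

    def parameters(self):
        return [self.theta, *self.mlp.parameters()]

    def forward(self, x: Tensor):
        if x.shape[1] != self.spec.in_features:
            raise ValueError(f"expected {self.spec.in_features} features, got {x.shape[1]}")
        skip = x @ self.theta
        hidden, nonlin = self.mlp.forward(x)
        return concat([hidden, skip], axis=1), skip + nonlin

    def apply_prox(self, step: float):
        """Hierarchical proximal step on (theta, first-layer weights) in place."""
        W1 = self.mlp.layers[0][0]
        th, w = hier_prox(self.theta.data.ravel(), W1.data.T,
                          self.spec.lambda_skip, self.spec.M, step)
        self.theta.data = th.reshape(-1, 1)
        W1.data = w.T


def lassonet_forward(x, net: LassoNet):
    x = x if isinstance(x, Tensor) else Tensor(x)
    return net.forward(x)


def hier_prox(theta, W1, lambda_skip, M, step=1.0):
    """Exact hierarchical proximal operator for the LassoNet constraint.

    Solves, independently per feature j,
        min_{t, w} 1/2 (t - theta_j)^2 + 1/2 ||w - W1[:, j]||^2
                   + step * lambda_skip * |t|
        s.t. ||w||_inf <= M |t|
    ``theta`` is (d,), ``W1`` is (hidden, d) with column j belonging to
    feature j. Guarantees theta'_j = 0 => W1'[:, j] = 0 and the infinity-norm
    constraint exactly.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    W1 = np.atleast_2d(np.asarray(W1, dtype=float))
    if W1.shape[1] != len(theta):
        raise ValueError("W1 must have one column per feature")
    k, d = W1.shape
    lam = lambda_skip * step
    absW_sorted = -np.sort(-np.abs(W1), axis=0)          # (k, d) descending
    cum = np.vstack([np.zeros((1, d)), np.cumsum(absW_sorted, axis=0)])  # (k+1, d)
    m = np.arange(k + 1)[:, None]
    w_m = (M / (1.0 + m * M**2)) * np.maximum(np.abs(theta)[None, :] + M * cum - lam, 0.0)
    lower = np.vstack([absW_sorted, np.zeros((1, d))])   # |v_(m+1)| for m = 0..k
    idx = np.sum(lower > w_m, axis=0)                    # first feasible m per feature
    w_star = w_m[idx, np.arange(d)]
    sign_theta = np.where(theta >= 0, 1.0, -1.0)
    theta_new = sign_theta * w_star / M
    W1_new = np.sign(W1) * np.minimum(np.abs(W1), w_star[None, :])
    return theta_new, W1_new


class NODE:
    """Neural oblivious decision ensemble head.

    Each oblivious tree shares one (softly selected) split feature and
    threshold across all nodes of a depth level; a sigmoid gate at
    temperature ``spec.temperature`` replaces the hard comparison, and the
    output is the expectation of the leaf responses under the induced
    product-of-gates leaf distribution. A layer averages its trees;
    additional layers receive the original input concatenated with all
    previous layer outputs, and the head output averages the layers.
    """

    def __init__(self, spec: NODESpec, rng=None):
        self.spec = spec.validate()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.layers = []
        d_in = spec.in_features
        for _ in range(spec.n_layers):
            layer = []
            for _t in range(spec.n_trees):
                layer.append({
                    "logits": Tensor.param(rng.normal(0, 0.5, (spec.depth, d_in))),
                    "thresh": Tensor.param(rng.normal(0, 0.5, (1, spec.depth))),
                    "leaves": Tensor.param(rng.normal(0, 0.5, (2 ** spec.depth,
                                                               spec.response_dim))),
                })
            self.layers.append(layer)
            d_in += spec.response_dim

    def parameters(self):
        return [p for layer in self.layers for tree in layer for p in tree.values()]

    def forward(self, x: Tensor):
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[1] != self.spec.in_features:
            raise ValueError(f"expected {self.spec.in_features} features, got {x.shape[1]}")
        temp = self.spec.temperature
        inp = x
        layer_outs = []
        for layer in self.layers:
            tree_outs = []
            for tree in layer:
                sel = tree["logits"].softmax(axis=-1)      # (depth, d_in)
                chosen = inp @ sel.T                        # (n, depth)
                g = ((chosen - tree["thresh"]) * (1.0 / temp)).sigmoid()
                probs = Tensor(np.ones((x.shape[0], 1)))
                for dep in range(self.spec.depth):
                    gd = g[:, dep:dep + 1]
                    probs = concat([probs * gd, probs * (1.0 - gd)], axis=1)
                tree_outs.append(probs @ tree["leaves"])    # (n, response_dim)
            out = tree_outs[0]
            for t in tree_outs[1:]:
                out = out + t
            out = out * (1.0 / len(tree_outs))
            layer_outs.append(out)
            inp = concat([inp, out], axis=1)
        total = layer_outs[0]
        for o in layer_outs[1:]:
            total = total + o
        return total * (1.0 / len(layer_outs))


def node_forward(x, node: NODE):
    return node.forward(x if isinstance(x, Tensor) else Tensor(x))


# --------------------------------------------------------------------------
# IPM penalty
# --------------------------------------------------------------------------
def _pairwise_sq_dists(a: Tensor, b: Tensor) -> Tensor:
    aa = (a * a).sum(axis=1, keepdims=True)        # (n, 1)
    bb = (b * b).sum(axis=1, keepdims=True).T      # (1, m)
    return aa + bb - 2.0 * (a @ b.T)


def ipm_penalty(batch: RepresentationBatch, bandwidth: float | None = None):
    """Squared MMD (RBF kernel, V-statistic) between the two treatment groups.

    Zero iff the two multisets of representations are identical; symmetric
    in the groups; differentiable in the representations. If a mini-batch
    happens to miss one group entirely the penalty is 0 with a warning.
    Bandwidth defaults to the median pairwise distance heuristic.
    """
    rep = batch.rep if isinstance(batch.rep, Tensor) else Tensor(batch.rep)
    t = batch.treatment
    mask1, mask0 = t == 1, t == 0
    if mask1.sum() == 0 or mask0.sum() == 0:
        warnings.warn("a treatment group is empty in this batch; IPM penalty skipped")
        return Tensor(0.0)
    a = rep[np.where(mask1)[0]]
    b = rep[np.where(mask0)[0]]
    if bandwidth is None:
        with np.errstate(invalid="ignore"):
            d2 = np.maximum(_pairwise_sq_dists(Tensor(a.data), Tensor(b.data)).data, 0.0)
        med = np.median(d2)
        bandwidth = float(np.sqrt(med / 2.0)) if med > 0 else 1.0
    two_s2 = 2.0 * bandwidth**2
    k_aa = ((_pairwise_sq_dists(a, a) * (-1.0 / two_s2)).exp()).mean()
    k_bb = ((_pairwise_sq_dists(b, b) * (-1.0 / two_s2)).exp()).mean()
    k_ab = ((_pairwise_sq_dists(a, b) * (-1.0 / two_s2)).exp()).mean()
    return k_aa + k_bb - 2.0 * k_ab
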