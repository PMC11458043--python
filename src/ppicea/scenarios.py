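"""Synthetic decision models and perturbed parameter sets.

Two test-harness generators, both first-class and seeded:

* ``generate_synthetic_model`` builds a random chance tree (bounded depth and
  branching, Dirichlet branch probabilities) whose terminal payoffs are drawn
  on the scales of the real model (costs up to 10^4 USD, QALY losses up to
  10).  The analytic expected cost and QALY loss are accumulated by direct
  probability-product summation *during generation*, independently of the
  engine's rollback, so the pair (stored expectation, engine rollback) forms
  an exact cross-check of the evaluation engine.

* ``perturb_parameters`` jitters every non-fixed base value within its
  sensitivity range, emulating region-specific input sets; the perturbed set
  is re-validated (the recommendation mix is renormalised to keep its
  sum-to-1 invariant).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np

from .parameters import (
    PARAMETER_SCHEMA,
    RECOMMENDATION_MIX,
    ModelParameters,
)
from .tree import ChanceNode, Leaf, Node

__all__ = ["SyntheticModel", "generate_synthetic_model", "perturb_parameters"]

_COST_SCALE = 1.0e4
_QALY_SCALE = 10.0


@dataclass(frozen=True)
class SyntheticModel:
    """A random chance tree with generation-time analytic expectations."""

    root: Node
    expected_cost: float
    expected_qaly_loss: float
    seed: int
    depth: int
    branching: int


def generate_synthetic_model(
    seed: int, depth: int = 3, branching: int = 3
) -> SyntheticModel:
    """Random probability tree with known closed-form expected payoffs.

    ``depth`` bounds the number of chance-node levels (>= 1) and
    ``branching`` the branches per node (>= 2).  Identical seeds give
    identical models.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if branching < 2:
        raise ValueError("branching must be >= 2")
    rng = np.random.default_rng(seed)
    total = {"cost": 0.0, "qaly": 0.0}

    def build(level: int, reach_prob: float) -> Node:
        # terminal payoff, accumulated analytically while generating
        if level >= depth or (level > 0 and rng.random() < 0.3):
            payoff = (rng.uniform(0.0, _COST_SCALE), rng.uniform(0.0, _QALY_SCALE))
            total["cost"] += reach_prob * payoff[0]
            total["qaly"] += reach_prob * payoff[1]
            return Leaf(payoff)
        n_branches = int(rng.integers(2, branching + 1))
        probs = rng.dirichlet(np.ones(n_branches))
        probs = probs / probs.sum()
        branches = tuple(
            (float(p), build(level + 1, reach_prob * float(p))) for p in probs
        )
        return ChanceNode(branches)

    root = build(0, 1.0)
    if isinstance(root, Leaf):  # guarantee at least one chance level
        root = ChanceNode(((1.0, root),))
    return SyntheticModel(
        root=root,
        expected_cost=total["cost"],
        expected_qaly_loss=total["qaly"],
        seed=seed,
        depth=depth,
        branching=branching,
    )


def perturb_parameters(
    params: ModelParameters, scale: float, seed: int
) -> ModelParameters:
    """Jitter each non-fixed base value within its range by fraction ``scale``.

    A uniform draw u in [-1, 1] moves the base toward the corresponding range
    endpoint by ``scale * |u|`` of the distance, so scale 0 is the identity
    and scale 1 can reach the endpoints.  The recommendation mix is
    renormalised (endpoints clipped to the ranges) and the perturbed set is
    revalidated; an invariant violation triggers a resample.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    rng = np.random.default_rng(seed)
    for _attempt in range(100):
        values = {}
        for name in PARAMETER_SCHEMA:
            pv = params[name]
            if pv.is_fixed or scale == 0.0:
                values[name] = pv
                continue
            u = rng.uniform(-1.0, 1.0)
            if u >= 0:
                base = pv.base + scale * u * (pv.high - pv.base)
            else:
                base = pv.base + scale * u * (pv.base - pv.low)
            base = min(max(base, pv.low), pv.high)
            values[name] = replace(pv, base=base)
        # keep the recommendation mix on the simplex
        mix_total = sum(values[n].base for n in RECOMMENDATION_MIX)
        if mix_total > 0:
            for n in RECOMMENDATION_MIX:
                pv = values[n]
                base = pv.base / mix_total
                values[n] = replace(
                    pv, base=base, low=min(pv.low, base), high=max(pv.high, base)
                )
        try:
            out = copy.copy(params)
            out.values = values
            out.validate()
            return out
        except Exception:
            continue
    raise RuntimeError("could not generate a valid perturbed parameter set")
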