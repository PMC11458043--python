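"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis re-evaluates the model with a single parameter set to each
end of its sensitivity range, all others at base case, and ranks parameters
by the spread of a tracked outcome (ICER by default; net monetary benefit is
the stabler choice when QALYs saved can cross zero).  A threshold flag marks
any parameter whose two endpoint evaluations disagree on the
cost-effectiveness verdict.

Probabilistic analysis draws every non-fixed parameter jointly from its
fitted distribution, evaluates **both** strategies on the same draw (common
random parameters — the incremental scatter is only meaningful per-draw),
and summarises incremental cost and QALYs saved with means, normal-theory
confidence intervals for the means, empirical percentile intervals of the
draws, and acceptability proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cea import evaluate_base_case, evaluate_realized, net_monetary_benefit
from .parameters import (
    PARAMETER_SCHEMA,
    ModelParameters,
    fit_all,
)
from .tree import TreeError

__all__ = [
    "OneWayRow",
    "PSAResult",
    "one_way_sa",
    "run_psa",
    "ceac",
]

_TRACKED = ("icer", "nmb", "incremental_cost", "qaly_saved")


@dataclass(frozen=True)
class OneWayRow:
    """One parameter's one-way excursion, all others at base case."""

    parameter: str
    low: float
    high: float
    outcome_at_low: float
    outcome_at_high: float
    cost_effective_at_low: bool
    cost_effective_at_high: bool
    threshold_crossed: bool

    @property
    def spread(self) -> float:
        return abs(self.outcome_at_high - self.outcome_at_low)


def _tracked_outcome(evaluation, which: str) -> float:
    cea = evaluation.cea
    if which == "icer":
        return math.nan if cea.icer is None else cea.icer
    if which == "nmb":
        return net_monetary_benefit(cea)
    if which == "incremental_cost":
        return cea.incremental_cost
    if which == "qaly_saved":
        return cea.qaly_saved
    raise ValueError(f"tracked_outcome must be one of {_TRACKED}, got {which!r}")


def one_way_sa(
    params: ModelParameters,
    tracked_outcome: str = "icer",
    wtp: float | None = None,
) -> list[OneWayRow]:
    """One row per non-fixed parameter, sorted by spread (tornado order)."""
    if tracked_outcome not in _TRACKED:
        raise ValueError(f"tracked_outcome must be one of {_TRACKED}")
    wtp = params.run.wtp_threshold_usd if wtp is None else wtp
    base_map = params.base_map()
    base_verdict = evaluate_base_case(params, wtp).cea.cost_effective_at_wtp

    rows: list[OneWayRow] = []
    for name in PARAMETER_SCHEMA:
        pv = params[name]
        if pv.is_fixed:
            continue
        endpoint_vals: list[float] = []
        endpoint_ce: list[bool] = []
        for bound in (pv.low, pv.high):
            realized = dict(base_map)
            realized[name] = bound
            evaluation = evaluate_realized(realized, params.run, wtp)
            endpoint_vals.append(_tracked_outcome(evaluation, tracked_outcome))
            endpoint_ce.append(evaluation.cea.cost_effective_at_wtp)
        rows.append(
            OneWayRow(
                parameter=name,
                low=pv.low,
                high=pv.high,
                outcome_at_low=endpoint_vals[0],
                outcome_at_high=endpoint_vals[1],
                cost_effective_at_low=endpoint_ce[0],
                cost_effective_at_high=endpoint_ce[1],
                threshold_crossed=(
                    endpoint_ce[0] != endpoint_ce[1]
                    or endpoint_ce[0] != base_verdict
                ),
            )
        )
    rows.sort(key=lambda r: r.spread, reverse=True)
    return rows


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass
class PSAResult:
    """Per-draw incremental outcomes of a Monte Carlo PSA."""

    incremental_cost: np.ndarray
    qaly_saved: np.ndarray
    uc_cost: np.ndarray
    uc_qaly_loss: np.ndarray
    dep_cost: np.ndarray
    dep_qaly_loss: np.ndarray
    wtp: float
    seed: int
    n_rejected: int = 0

    @property
    def n_draws(self) -> int:
        return self.incremental_cost.size

    @property
    def nmb(self) -> np.ndarray:
        return self.wtp * self.qaly_saved - self.incremental_cost

    # -- acceptability proportions -------------------------------------------
    @property
    def proportion_qaly_saving(self) -> float:
        return float(np.mean(self.qaly_saved > 0.0))

    @property
    def proportion_cost_saving(self) -> float:
        return float(np.mean(self.incremental_cost < 0.0))

    @property
    def proportion_cost_effective(self) -> float:
        return float(np.mean(self.nmb > 0.0))

    def summary(self, ci_level: float = 0.95) -> dict:
        """Means with normal-theory CIs of the mean, and percentile intervals
        of the per-draw distributions."""
        z = stats.norm.ppf(0.5 + ci_level / 2.0)
        lo_q, hi_q = 100 * (0.5 - ci_level / 2.0), 100 * (0.5 + ci_level / 2.0)
        out: dict = {"n_draws": int(self.n_draws), "seed": self.seed,
                     "wtp": self.wtp, "n_rejected": self.n_rejected}
        for label, arr in (
            ("incremental_cost", self.incremental_cost),
            ("cost_saved", -self.incremental_cost),
            ("qaly_saved", self.qaly_saved),
        ):
            mean = float(arr.mean())
            se = float(arr.std(ddof=1) / np.sqrt(self.n_draws)) if self.n_draws > 1 else 0.0
            out[label] = {
                "mean": mean,
                "mean_ci": [mean - z * se, mean + z * se],
                "percentile_interval": [
                    float(np.percentile(arr, lo_q)),
                    float(np.percentile(arr, hi_q)),
                ],
            }
        out["proportions"] = {
            "qaly_saving": self.proportion_qaly_saving,
            "cost_saving": self.proportion_cost_saving,
            "cost_effective_at_wtp": self.proportion_cost_effective,
        }
        return out


def run_psa(
    params: ModelParameters,
    n_draws: int,
    seed: int,
    wtp: float | None = None,
    sd_scale: float = 1.0,
) -> PSAResult:
    """Monte Carlo PSA: joint parameter draws, both strategies per draw.

    A draw whose adverse-event probabilities cannot form a valid tree (their
    sum reaching 1 for some exposure) is rejected and redrawn from the same
    stream; the count is recorded in ``n_rejected``.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    wtp = params.run.wtp_threshold_usd if wtp is None else wtp
    specs = fit_all(params, sd_scale)
    sampled = [n for n in PARAMETER_SCHEMA if specs[n].family != "degenerate"]
    rng = np.random.default_rng(seed)

    inc_cost = np.empty(n_draws)
    saved = np.empty(n_draws)
    uc_cost = np.empty(n_draws)
    uc_loss = np.empty(n_draws)
    dep_cost = np.empty(n_draws)
    dep_loss = np.empty(n_draws)

    base_map = params.base_map()
    n_rejected = 0

    for i in range(n_draws):
        while True:
            realized = dict(base_map)
            for name in sampled:
                realized[name] = float(specs[name].sample(rng))
            # the recommendation mix is renormalised inside the tree builder,
            # so a degenerate PSA reproduces the base case bit-identically
            try:
                evaluation = evaluate_realized(realized, params.run, wtp)
            except TreeError:
                n_rejected += 1
                continue
            break
        inc_cost[i] = evaluation.cea.incremental_cost
        saved[i] = evaluation.cea.qaly_saved
        uc_cost[i] = evaluation.usual_care.expected_cost
        uc_loss[i] = evaluation.usual_care.expected_qaly_loss
        dep_cost[i] = evaluation.deprescribing.expected_cost
        dep_loss[i] = evaluation.deprescribing.expected_qaly_loss

    return PSAResult(
        incremental_cost=inc_cost,
        qaly_saved=saved,
        uc_cost=uc_cost,
        uc_qaly_loss=uc_loss,
        dep_cost=dep_cost,
        dep_qaly_loss=dep_loss,
        wtp=wtp,
        seed=seed,
        n_rejected=n_rejected,
    )


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability: P(NMB > 0) along a WTP grid."""
    grid = list(wtp_grid)
    if not grid:
        raise ValueError("wtp_grid must be non-empty")
    out = []
    for w in grid:
        nmb = w * psa.qaly_saved - psa.incremental_cost
        out.append((float(w), float(np.mean(nmb > 0.0))))
    return out
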