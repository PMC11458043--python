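"""Expected-value rollup, incremental analysis, dominance and net benefit.

A strategy's expected cost and expected QALY loss are probability-weighted
sums over its terminal paths.  The incremental comparison reports

* incremental cost  ΔC = C(intervention) − C(comparator),
* QALYs saved       ΔE = L(comparator) − L(intervention),
* ICER = ΔC / ΔE (reported even under dominance, as is conventional in
  published tables; the dominance flag, not the ICER's sign, carries the
  verdict),
* a dominance classification, and
* cost-effectiveness at a willingness-to-pay (WTP) threshold: dominant, or a
  trade-off with ICER ≤ WTP.

Net monetary benefit NMB = WTP·ΔE − ΔC is positive exactly when the
intervention is cost-effective at that WTP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .parameters import ModelParameters, RunSettings
from .payoffs import PathOutcome, path_outcome
from .tree import Strategy, TerminalPath, strategy_paths

__all__ = [
    "Dominance",
    "StrategyResult",
    "CEAResult",
    "ModelEvaluation",
    "evaluate_strategy",
    "incremental_analysis",
    "net_monetary_benefit",
    "evaluate_realized",
    "evaluate_base_case",
]

_PROB_TOL = 1e-9


class Dominance(str, Enum):
    dominant = "dominant"        # saves QALYs at lower cost
    dominated = "dominated"      # loses QALYs at higher cost (or ties unfavourably)
    trade_off = "trade_off"      # more effective and more costly (or vice versa)
    equivalent = "equivalent"    # identical cost and effect


@dataclass(frozen=True)
class StrategyResult:
    """Expected one-year cost and QALY loss of one strategy."""

    strategy: str
    expected_cost: float
    expected_qaly_loss: float


@dataclass(frozen=True)
class CEAResult:
    incremental_cost: float
    qaly_saved: float
    icer: float | None
    dominance: Dominance
    cost_effective_at_wtp: bool
    wtp: float


def evaluate_strategy(
    paths: Sequence[TerminalPath],
    outcomes: Sequence[PathOutcome],
    label: str = "",
) -> StrategyResult:
    """Probability-weighted expected cost and QALY loss over terminal paths."""
    if len(paths) == 0:
        raise ValueError("cannot evaluate a strategy with no terminal paths")
    if len(paths) != len(outcomes):
        raise ValueError("paths and outcomes must align")
    total_p = math.fsum(p.probability for p in paths)
    if abs(total_p - 1.0) > _PROB_TOL:
        raise ValueError(f"terminal probabilities sum to {total_p!r}, expected 1")
    cost = math.fsum(p.probability * o.cost_usd for p, o in zip(paths, outcomes))
    loss = math.fsum(p.probability * o.qaly_loss for p, o in zip(paths, outcomes))
    return StrategyResult(label, cost, loss)


def incremental_analysis(
    intervention: StrategyResult,
    comparator: StrategyResult,
    wtp: float,
) -> CEAResult:
    """Incremental cost, QALYs saved, ICER and the dominance verdict."""
    for r in (intervention, comparator):
        if not (math.isfinite(r.expected_cost) and math.isfinite(r.expected_qaly_loss)):
            raise ValueError("strategy results must be finite")
    d_cost = intervention.expected_cost - comparator.expected_cost
    saved = comparator.expected_qaly_loss - intervention.expected_qaly_loss
    icer = d_cost / saved if saved != 0.0 else None

    if saved > 0.0 and d_cost < 0.0:
        dom = Dominance.dominant
    elif saved < 0.0 and d_cost > 0.0:
        dom = Dominance.dominated
    elif saved == 0.0:
        if d_cost == 0.0:
            dom = Dominance.equivalent
        else:  # equal effect: verdict on cost alone
            dom = Dominance.dominant if d_cost < 0.0 else Dominance.dominated
    elif d_cost == 0.0:
        dom = Dominance.dominant if saved > 0.0 else Dominance.dominated
    else:
        dom = Dominance.trade_off

    if dom is Dominance.dominant:
        ce = True
    elif dom in (Dominance.dominated, Dominance.equivalent):
        ce = False
    elif saved > 0.0:  # costs more, saves QALYs
        ce = icer <= wtp
    else:  # saves cost, loses QALYs: cost-effective if savings outweigh loss
        ce = -d_cost >= wtp * (-saved)
    return CEAResult(d_cost, saved, icer, dom, ce, wtp)


def net_monetary_benefit(cea: CEAResult, wtp: float | None = None) -> float:
    """NMB = WTP × QALYs saved − incremental cost; > 0 ⇔ cost-effective."""
    w = cea.wtp if wtp is None else wtp
    return w * cea.qaly_saved - cea.incremental_cost


# ---------------------------------------------------------------------------
# Whole-model evaluation


@dataclass
class ModelEvaluation:
    """Both strategies evaluated at one parameter realisation."""

    usual_care: StrategyResult
    deprescribing: StrategyResult
    cea: CEAResult
    paths: dict[Strategy, list[TerminalPath]]
    outcomes: dict[Strategy, list[PathOutcome]]

    def summary(self) -> str:
        uc, dep, cea = self.usual_care, self.deprescribing, self.cea
        icer = "-" if cea.icer is None else f"{cea.icer:,.0f}"
        verdict = cea.dominance.value.replace("_", " ")
        lines = [
            "Cost-effectiveness of PPI deprescribing vs usual care (1-year horizon)",
            "=" * 72,
            f"{'Strategy':<20}{'Cost (USD)':>12}{'Incr. cost':>12}"
            f"{'QALY loss':>12}{'QALY saved':>12}",
            "-" * 72,
            f"{'Usual care':<20}{uc.expected_cost:>12,.1f}{'-':>12}"
            f"{uc.expected_qaly_loss:>12.4f}{'-':>12}",
            f"{'Deprescribing':<20}{dep.expected_cost:>12,.1f}"
            f"{cea.incremental_cost:>12,.1f}{dep.expected_qaly_loss:>12.4f}"
            f"{cea.qaly_saved:>12.4f}",
            "-" * 72,
            f"ICER: {icer} USD/QALY ({verdict})",
            f"Cost-effective at WTP {cea.wtp:,.0f} USD/QALY: "
            f"{'yes' if cea.cost_effective_at_wtp else 'no'}   "
            f"NMB: {net_monetary_benefit(cea):,.1f} USD",
        ]
        return "\n".join(lines)


def evaluate_realized(
    realized: Mapping[str, float],
    run: RunSettings,
    wtp: float | None = None,
) -> ModelEvaluation:
    """Evaluate both strategies on one (shared) parameter realisation."""
    wtp = run.wtp_threshold_usd if wtp is None else wtp
    paths: dict[Strategy, list[TerminalPath]] = {}
    outcomes: dict[Strategy, list[PathOutcome]] = {}
    results: dict[Strategy, StrategyResult] = {}
    for strategy in (Strategy.usual_care, Strategy.deprescribing):
        ps = strategy_paths(strategy, realized)
        os_ = [path_outcome(p.state, realized, run) for p in ps]
        paths[strategy], outcomes[strategy] = ps, os_
        results[strategy] = evaluate_strategy(ps, os_, strategy.value)
    cea = incremental_analysis(
        results[Strategy.deprescribing], results[Strategy.usual_care], wtp
    )
    return ModelEvaluation(
        usual_care=results[Strategy.usual_care],
        deprescribing=results[Strategy.deprescribing],
        cea=cea,
        paths=paths,
        outcomes=outcomes,
    )


def evaluate_base_case(
    params: ModelParameters, wtp: float | None = None
) -> ModelEvaluation:
    """Evaluate the model with every parameter at its base-case value."""
    return evaluate_realized(params.base_map(), params.run, wtp)
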