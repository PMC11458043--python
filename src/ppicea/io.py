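"""Tabular exports: path table, base-case table, tornado, PSA scatter, CEAC."""

from __future__ import annotations

import pandas as pd

from .cea import ModelEvaluation, net_monetary_benefit
from .sensitivity import OneWayRow, PSAResult
from .tree import Strategy

__all__ = [
    "path_table",
    "base_case_table",
    "tornado_table",
    "psa_scatter_table",
    "ceac_table",
]


def path_table(evaluation: ModelEvaluation) -> pd.DataFrame:
    """One row per terminal path: state fields, probability, cost, QALY loss."""
    rows = []
    for strategy in (Strategy.usual_care, Strategy.deprescribing):
        for path, outcome in zip(
            evaluation.paths[strategy], evaluation.outcomes[strategy]
        ):
            s = path.state
            rows.append(
                {
                    "strategy": s.strategy.value,
                    "triage": s.triage.value,
                    "rebound": s.rebound,
                    "adverse_event": s.adverse_event.value,
                    "ae_setting": s.ae_setting.value,
                    "died": s.died,
                    "probability": path.probability,
                    "cost_usd": outcome.cost_usd,
                    "qaly_loss": outcome.qaly_loss,
                }
            )
    return pd.DataFrame(rows)


def base_case_table(evaluation: ModelEvaluation) -> pd.DataFrame:
    """Two-row strategy comparison in the conventional results layout."""
    cea = evaluation.cea
    icer = None if cea.icer is None else round(cea.icer, 2)
    return pd.DataFrame(
        [
            {
                "strategy": "usual_care",
                "cost_usd": evaluation.usual_care.expected_cost,
                "incremental_cost_usd": None,
                "qaly_loss": evaluation.usual_care.expected_qaly_loss,
                "qaly_saved": None,
                "icer_usd_per_qaly": None,
                "dominance": None,
                "nmb_usd": None,
            },
            {
                "strategy": "deprescribing",
                "cost_usd": evaluation.deprescribing.expected_cost,
                "incremental_cost_usd": cea.incremental_cost,
                "qaly_loss": evaluation.deprescribing.expected_qaly_loss,
                "qaly_saved": cea.qaly_saved,
                "icer_usd_per_qaly": icer,
                "dominance": cea.dominance.value,
                "nmb_usd": net_monetary_benefit(cea),
            },
        ]
    )


def tornado_table(rows: list[OneWayRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "low": r.low,
                "high": r.high,
                "outcome_at_low": r.outcome_at_low,
                "outcome_at_high": r.outcome_at_high,
                "spread": r.spread,
                "cost_effective_at_low": r.cost_effective_at_low,
                "cost_effective_at_high": r.cost_effective_at_high,
                "threshold_crossed": r.threshold_crossed,
            }
            for r in rows
        ]
    )


def psa_scatter_table(psa: PSAResult) -> pd.DataFrame:
    """Per-draw incremental outcomes (the scatter-plot data)."""
    return pd.DataFrame(
        {
            "draw": range(psa.n_draws),
            "qaly_saved": psa.qaly_saved,
            "incremental_cost_usd": psa.incremental_cost,
        }
    )


def ceac_table(points: list[tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(points, columns=["wtp_usd_per_qaly", "probability_cost_effective"])
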