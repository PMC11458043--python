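"""One-year cost and QALY-loss payoffs for every terminal tree path.

Costs are direct medical costs in USD: a year of the effective drug regimen
(pro-rated by days for reinstated patients), adverse-event management
(hospital bed-days, or clinic visits for outpatient pneumonia), and — in the
deprescribing arm only — the pharmacist service cost, charged once per
patient evaluated.

QALY losses relative to a symptom-free year at the age-specific utility:
disutility × episode duration for rebound and adverse-event episodes, plus a
discounted-lifetime loss (utility × annuity of the remaining life expectancy)
for deaths.  The one-year horizon means costs are not discounted; only the
stream of life-years lost to death is, at the configured annual rate.

Conventions: medication costs pro-rate months at 30.4375 days/month (a
365.25-day drug year); episode QALY losses divide days by 365.  Patients who
die are still charged a full year of medication (the mortality probabilities
are small), and a death replaces any post-event disutility accrual
(e.g. the pneumonia convalescence period) but not the in-episode loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .parameters import RunSettings
from .tree import (
    AESetting,
    AdverseEvent,
    PathState,
    Regimen,
    Strategy,
    Triage,
    effective_exposure,
    interim_regimen,
)

__all__ = [
    "PathOutcome",
    "medication_cost",
    "adverse_event_cost",
    "deprescribing_service_cost",
    "episode_qaly_loss",
    "death_qaly_loss",
    "annuity_factor",
    "path_outcome",
]

DAYS_PER_MONTH = 30.4375
DAYS_PER_DRUG_YEAR = 12 * DAYS_PER_MONTH  # 365.25
DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class PathOutcome:
    """One-year cost (USD) and QALY loss attached to a terminal path."""

    cost_usd: float
    qaly_loss: float


def _monthly_cost(regimen: Regimen, realized: Mapping[str, float]) -> float:
    if regimen in (Regimen.ppi_standard, Regimen.ppi_reinstated):
        return realized["cost_ppi_standard_monthly"]
    if regimen is Regimen.ppi_low:
        return realized["cost_ppi_low_monthly"]
    if regimen is Regimen.h2ra:
        return realized["cost_h2ra_monthly"]
    return 0.0


def medication_cost(
    exposure: Regimen,
    realized: Mapping[str, float],
    run: RunSettings,
    interim: Regimen | None = None,
) -> float:
    """Drug-acquisition cost of the year-long regimen.

    A reinstated patient spends ``rebound_onset_days`` on the ``interim``
    (deprescribed) regimen and the remainder of the drug year back on
    standard-dose PPI.
    """
    if exposure is Regimen.ppi_reinstated:
        onset = min(run.rebound_onset_days, DAYS_PER_DRUG_YEAR)
        interim = Regimen.none if interim is None else interim
        daily_interim = _monthly_cost(interim, realized) / DAYS_PER_MONTH
        daily_standard = realized["cost_ppi_standard_monthly"] / DAYS_PER_MONTH
        return daily_interim * onset + daily_standard * (DAYS_PER_DRUG_YEAR - onset)
    return 12.0 * _monthly_cost(exposure, realized)


def adverse_event_cost(state: PathState, realized: Mapping[str, float]) -> float:
    """Management cost of the adverse event on this path.

    Hospitalized events cost length-of-stay × daily bed cost (deaths occur
    in hospital, so the admission is still charged); outpatient pneumonia
    costs the configured number of clinic visits; non-hospitalized
    hypomagnesemia has no modelled utilisation.
    """
    event, setting = state.adverse_event, state.ae_setting
    if event is AdverseEvent.none:
        return 0.0
    if setting is AESetting.hospitalized:
        los = {
            AdverseEvent.hypomagnesemia: realized["los_hypomag_days"],
            AdverseEvent.pneumonia: realized["los_pneumonia_days"],
            AdverseEvent.cdi: realized["los_cdi_days"],
        }[event]
        return los * realized["cost_hosp_per_day"]
    if event is AdverseEvent.pneumonia:  # outpatient
        return realized["n_clinic_visits_pneumonia"] * realized["cost_clinic_visit"]
    return 0.0  # non-hospitalized hypomagnesemia


def deprescribing_service_cost(
    salary_monthly: float,
    minutes_per_case: float,
    working_minutes_per_month: float,
) -> float:
    """Pharmacist-time cost of one deprescribing evaluation."""
    if working_minutes_per_month <= 0:
        raise ValueError("working_minutes_per_month must be > 0")
    return salary_monthly / working_minutes_per_month * minutes_per_case


def episode_qaly_loss(disutility: float, duration_days: float) -> float:
    """QALY decrement of a transient health state: disutility × days/365."""
    if not (0.0 <= disutility <= 1.0):
        raise ValueError(f"disutility {disutility} outside [0, 1]")
    if duration_days < 0:
        raise ValueError("duration must be >= 0")
    return disutility * duration_days / DAYS_PER_YEAR


def annuity_factor(rate: float, years: float) -> float:
    """Present value of one unit per year over ``years`` at annual ``rate``."""
    if years <= 0:
        return 0.0
    if rate == 0.0:
        return years
    return (1.0 - (1.0 + rate) ** (-years)) / rate


def death_qaly_loss(utility: float, life_expectancy_years: float, discount_rate: float) -> float:
    """Discounted QALYs lost to a death: utility × annuity(remaining years)."""
    if not (0.0 <= utility <= 1.0):
        raise ValueError(f"utility {utility} outside [0, 1]")
    if life_expectancy_years < 0:
        raise ValueError("life expectancy must be >= 0")
    if discount_rate < 0:
        raise ValueError("discount rate must be >= 0")
    return utility * annuity_factor(discount_rate, life_expectancy_years)


def _ae_qaly_loss(state: PathState, realized: Mapping[str, float]) -> float:
    event, setting = state.adverse_event, state.ae_setting
    if event is AdverseEvent.none:
        return 0.0
    if event is AdverseEvent.hypomagnesemia:
        if setting is AESetting.hospitalized:
            return episode_qaly_loss(
                realized["disutil_hosp_hypomag"], realized["los_hypomag_days"]
            )
        return 0.0  # non-hospitalized hypomagnesemia: no modelled episode
    if event is AdverseEvent.pneumonia:
        if setting is AESetting.outpatient:
            return episode_qaly_loss(
                realized["disutil_amb_pneumonia"], realized["outpatient_pneumonia_days"]
            )
        loss = episode_qaly_loss(
            realized["disutil_hosp_pneumonia"], realized["los_pneumonia_days"]
        )
        if not state.died:  # survivors convalesce at the ambulatory disutility
            loss += episode_qaly_loss(
                realized["disutil_amb_pneumonia"],
                realized["convalescence_pneumonia_days"],
            )
        return loss
    # CDI (always hospitalized)
    return episode_qaly_loss(realized["disutil_cdi"], realized["los_cdi_days"])


def path_outcome(
    state: PathState, realized: Mapping[str, float], run: RunSettings
) -> PathOutcome:
    """Compose the one-year cost and QALY loss of a terminal path."""
    exposure = effective_exposure(state)
    interim = interim_regimen(state.triage) if state.rebound else None
    cost = medication_cost(exposure, realized, run, interim=interim)
    cost += adverse_event_cost(state, realized)
    if state.strategy is Strategy.deprescribing:
        cost += deprescribing_service_cost(
            realized["pharmacist_salary_monthly"],
            realized["deprescribe_minutes_per_case"],
            run.pharmacist_working_minutes_per_month,
        )

    qaly = _ae_qaly_loss(state, realized)
    if state.rebound:
        disutil = (
            realized["disutil_relapse_off_meds"]
            if state.triage is Triage.discontinued
            else realized["disutil_relapse_on_meds"]
        )
        qaly += episode_qaly_loss(disutil, run.rebound_onset_days)
    if state.died:
        qaly += death_qaly_loss(
            realized["utility_age65plus"],
            run.life_expectancy(realized["age_years"]),
            run.discount_rate_annual,
        )
    return PathOutcome(cost_usd=cost, qaly_loss=qaly)
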