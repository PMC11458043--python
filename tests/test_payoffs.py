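"""Cost and QALY-loss payoffs attached to terminal paths."""

import math

import pytest

import ppicea as pp
from ppicea.payoffs import DAYS_PER_MONTH, DAYS_PER_DRUG_YEAR
from ppicea.tree import (
    AESetting,
    AdverseEvent,
    PathState,
    Regimen,
    Strategy,
    Triage,
    walk_paths,
    build_strategy_tree,
)
from conftest import override_params


def _state(strategy=Strategy.usual_care, triage=Triage.appropriate, rebound=False,
           event=AdverseEvent.none, setting=AESetting.not_applicable, died=False):
    return PathState(strategy, triage, rebound, event, setting, died)


# ---------------------------------------------------------------------------
# Medication cost


def test_standard_ppi_year_costs_twelve_months(base_realized, params):
    assert pp.medication_cost(Regimen.ppi_standard, base_realized, params.run) == 12 * 54


def test_discontinued_without_rebound_costs_nothing(base_realized, params):
    assert pp.medication_cost(Regimen.none, base_realized, params.run) == 0.0


def test_reinstated_regimen_prorated_by_days(base_realized, params):
    """20 days off drug, then standard PPI for the remaining 345.25 days of
    the 365.25-day drug year."""
    got = pp.medication_cost(Regimen.ppi_reinstated, base_realized, params.run,
                             interim=Regimen.none)
    expected = 54 / DAYS_PER_MONTH * (DAYS_PER_DRUG_YEAR - 20)
    assert got == pytest.approx(expected, rel=1e-12)
    # interim low-dose PPI adds 20 days at the low-dose daily rate
    got_low = pp.medication_cost(Regimen.ppi_reinstated, base_realized, params.run,
                                 interim=Regimen.ppi_low)
    assert got_low == pytest.approx(expected + 42 / DAYS_PER_MONTH * 20, rel=1e-12)


# ---------------------------------------------------------------------------
# Adverse-event and service cost


@pytest.mark.parametrize(
    "event, setting, died, expected",
    [
        (AdverseEvent.cdi, AESetting.hospitalized, False, 8 * 654),
        (AdverseEvent.cdi, AESetting.hospitalized, True, 8 * 654),
        (AdverseEvent.pneumonia, AESetting.outpatient, False, 3 * 57),
        (AdverseEvent.pneumonia, AESetting.hospitalized, False, 9.8 * 654),
        (AdverseEvent.hypomagnesemia, AESetting.hospitalized, False, 6 * 654),
        (AdverseEvent.hypomagnesemia, AESetting.outpatient, False, 0.0),
        (AdverseEvent.none, AESetting.not_applicable, False, 0.0),
    ],
)
def test_adverse_event_cost(base_realized, event, setting, died, expected):
    state = _state(event=event, setting=setting, died=died)
    assert pp.adverse_event_cost(state, base_realized) == pytest.approx(expected)


def test_service_cost_is_salary_prorated_by_minutes():
    assert pp.deprescribing_service_cost(10918, 34, 10560) == pytest.approx(
        10918 / 10560 * 34, rel=1e-12
    )
    assert pp.deprescribing_service_cost(10918, 0, 10560) == 0.0
    # doubling the working-minutes divisor halves the cost
    assert pp.deprescribing_service_cost(10918, 34, 21120) == pytest.approx(
        pp.deprescribing_service_cost(10918, 34, 10560) / 2
    )


# ---------------------------------------------------------------------------
# QALY losses


def test_episode_qaly_loss_examples():
    assert pp.episode_qaly_loss(0.3985, 8) == pytest.approx(0.3985 * 8 / 365, rel=1e-12)
    assert pp.episode_qaly_loss(0.5, 0) == 0.0


def test_hospitalized_pneumonia_survivor_accrues_convalescence(base_realized, params):
    state = _state(event=AdverseEvent.pneumonia, setting=AESetting.hospitalized)
    outcome = pp.path_outcome(state, base_realized, params.run)
    expected = 0.5597 * 9.8 / 365 + 0.3013 * 31 / 365
    assert outcome.qaly_loss == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(0.040617, abs=5e-7)


def test_death_qaly_loss_closed_form():
    assert pp.death_qaly_loss(0.81, 10, 0.0) == pytest.approx(8.1, rel=1e-12)
    annuity = (1 - 1.03 ** -10) / 0.03
    assert pp.death_qaly_loss(0.81, 10, 0.03) == pytest.approx(0.81 * annuity, rel=1e-12)
    assert 0.81 * annuity == pytest.approx(6.90946, abs=5e-6)
    assert pp.death_qaly_loss(0.81, 0, 0.03) == 0.0


def test_annuity_continuous_in_life_expectancy():
    a = pp.annuity_factor(0.03, 9.999999)
    b = pp.annuity_factor(0.03, 10.000001)
    assert abs(a - b) < 1e-5


# ---------------------------------------------------------------------------
# Path-outcome composition


def test_usual_care_uneventful_year(base_realized, params):
    outcome = pp.path_outcome(_state(), base_realized, params.run)
    assert outcome.cost_usd == pytest.approx(648.0)
    assert outcome.qaly_loss == 0.0


def test_successful_discontinuation_costs_only_the_service(base_realized, params):
    state = _state(strategy=Strategy.deprescribing, triage=Triage.discontinued)
    outcome = pp.path_outcome(state, base_realized, params.run)
    assert outcome.cost_usd == pytest.approx(pp.deprescribing_service_cost(10918, 34, 10560))
    assert outcome.qaly_loss == 0.0


def test_cdi_death_composes_episode_and_lifetime_loss(base_realized, params):
    state = _state(event=AdverseEvent.cdi, setting=AESetting.hospitalized, died=True)
    outcome = pp.path_outcome(state, base_realized, params.run)
    assert outcome.cost_usd == pytest.approx(648 + 5232, rel=1e-12)
    le = params.run.life_expectancy(80.0)
    expected = 0.3985 * 8 / 365 + pp.death_qaly_loss(0.81, le, 0.03)
    assert outcome.qaly_loss == pytest.approx(expected, rel=1e-12)


def test_rebound_disutility_depends_on_remaining_medication(base_realized, params):
    off = pp.path_outcome(
        _state(strategy=Strategy.deprescribing, triage=Triage.discontinued, rebound=True),
        base_realized, params.run)
    on = pp.path_outcome(
        _state(strategy=Strategy.deprescribing, triage=Triage.dose_reduced, rebound=True),
        base_realized, params.run)
    assert off.qaly_loss == pytest.approx(0.0737 * 20 / 365, rel=1e-12)
    assert on.qaly_loss == pytest.approx(0.0486 * 20 / 365, rel=1e-12)


def test_death_paths_lose_more_qalys_than_surviving_siblings(base_realized, params):
    for event in (AdverseEvent.pneumonia, AdverseEvent.cdi):
        survive = pp.path_outcome(
            _state(event=event, setting=AESetting.hospitalized, died=False),
            base_realized, params.run)
        die = pp.path_outcome(
            _state(event=event, setting=AESetting.hospitalized, died=True),
            base_realized, params.run)
        assert die.qaly_loss > survive.qaly_loss


def test_all_outcomes_finite_and_nonnegative(params):
    for seed in range(3):
        realized = pp.sample_parameters(params, seed)
        for strategy in Strategy:
            for path in pp.strategy_paths(strategy, realized):
                o = pp.path_outcome(path.state, realized, params.run)
                assert math.isfinite(o.cost_usd) and o.cost_usd >= 0.0
                assert math.isfinite(o.qaly_loss) and o.qaly_loss >= 0.0


def test_no_disutility_no_mortality_means_no_qaly_loss(params):
    painless = override_params(
        params,
        disutil_relapse_on_meds=0.0, disutil_relapse_off_meds=0.0,
        disutil_hosp_hypomag=0.0, disutil_hosp_pneumonia=0.0,
        disutil_amb_pneumonia=0.0, disutil_cdi=0.0,
        p_mort_cdi=0.0, p_mort_pneumonia=0.0,
    )
    ev = pp.evaluate_base_case(painless)
    assert ev.usual_care.expected_qaly_loss == pytest.approx(0.0, abs=1e-15)
    assert ev.deprescribing.expected_qaly_loss == pytest.approx(0.0, abs=1e-15)


def test_expected_cost_decomposes_into_components(params, base_realized, base_eval):
    """Accounting identity: expected strategy cost equals the sum of expected
    medication, adverse-event and service components."""
    from ppicea.payoffs import (adverse_event_cost, deprescribing_service_cost,
                                medication_cost)
    from ppicea.tree import effective_exposure, interim_regimen

    for strategy in Strategy:
        root = build_strategy_tree(strategy, base_realized)
        med = ae = svc = 0.0
        for prob, state in walk_paths(root):
            interim = interim_regimen(state.triage) if state.rebound else None
            med += prob * medication_cost(
                effective_exposure(state), base_realized, params.run, interim=interim)
            ae += prob * adverse_event_cost(state, base_realized)
            if strategy is Strategy.deprescribing:
                svc += prob * deprescribing_service_cost(10918, 34, 10560)
        total = (base_eval.usual_care if strategy is Strategy.usual_care
                 else base_eval.deprescribing).expected_cost
        assert med + ae + svc == pytest.approx(total, rel=1e-12)
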