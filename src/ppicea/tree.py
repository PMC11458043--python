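"""Decision-tree engine: structure, path enumeration and rollback.

Two strategies are compared over a one-year horizon:

* **usual care** — every patient continues standard-dose PPI;
* **deprescribing** — a pharmacist reviews every patient; inappropriate use
  triggers one of three recommendations (discontinue, reduce dose, switch to
  an H2-receptor antagonist), which the prescriber may or may not accept.
  After an accepted deprescribing action, GERD rebound may occur, in which
  case the standard-dose PPI regimen is reinstated.

Every resulting drug exposure then branches over three mutually exclusive
adverse events — hypomagnesemia, pneumonia and Clostridium difficile
infection — with care-setting (outpatient/hospitalized) and, for hospitalized
pneumonia and CDI, survival branches.  Adverse-event probabilities in PPI
users are derived from the baseline (non-user) yearly rates and exposure
odds ratios on the odds scale.

The module exposes a tiny generic chance-node representation (`ChanceNode`,
`Leaf`) used both by the real model and by randomly generated synthetic
models, with two evaluation routes that must agree exactly: `walk_paths`
(brute-force terminal-path enumeration) and `rollback` (recursive expected
value).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Iterable, Mapping

__all__ = [
    "Strategy",
    "Triage",
    "AdverseEvent",
    "AESetting",
    "Regimen",
    "PathState",
    "TerminalPath",
    "Leaf",
    "ChanceNode",
    "TreeError",
    "odds_ratio_to_probability",
    "effective_exposure",
    "interim_regimen",
    "build_strategy_tree",
    "strategy_paths",
    "walk_paths",
    "rollback",
]


class TreeError(ValueError):
    """Structural failure while building or evaluating a tree."""


class Strategy(str, Enum):
    deprescribing = "deprescribing"
    usual_care = "usual_care"


class Triage(str, Enum):
    appropriate = "appropriate"
    inappropriate_not_accepted = "inappropriate_not_accepted"
    discontinued = "discontinued"
    dose_reduced = "dose_reduced"
    switched = "switched"


class AdverseEvent(str, Enum):
    none = "none"
    hypomagnesemia = "hypomagnesemia"
    pneumonia = "pneumonia"
    cdi = "cdi"


class AESetting(str, Enum):
    not_applicable = "not_applicable"
    outpatient = "outpatient"
    hospitalized = "hospitalized"


class Regimen(str, Enum):
    ppi_standard = "ppi_standard"
    ppi_low = "ppi_low"
    h2ra = "h2ra"
    none = "none"
    ppi_reinstated = "ppi_reinstated"


_DEPRESCRIBED = frozenset(
    {Triage.discontinued, Triage.dose_reduced, Triage.switched}
)


@dataclass(frozen=True)
class PathState:
    """Terminal health-state description of one tree path."""

    strategy: Strategy
    triage: Triage
    rebound: bool
    adverse_event: AdverseEvent
    ae_setting: AESetting
    died: bool

    def __post_init__(self) -> None:
        if self.rebound and self.triage not in _DEPRESCRIBED:
            raise TreeError("rebound requires a preceding deprescribing action")
        if self.strategy is Strategy.usual_care and self.triage is not Triage.appropriate:
            raise TreeError("usual care has no deprescribing triage")
        if self.died:
            if self.adverse_event not in (AdverseEvent.pneumonia, AdverseEvent.cdi):
                raise TreeError("death occurs only with pneumonia or CDI")
            if self.ae_setting is not AESetting.hospitalized:
                raise TreeError("death occurs only in hospitalized patients")
        if self.adverse_event is AdverseEvent.none:
            if self.ae_setting is not AESetting.not_applicable:
                raise TreeError("no adverse event implies no care setting")
        elif self.ae_setting is AESetting.not_applicable:
            raise TreeError("an adverse event requires a care setting")
        if self.adverse_event is AdverseEvent.cdi and self.ae_setting is not AESetting.hospitalized:
            raise TreeError("CDI patients are hospitalized")


@dataclass(frozen=True)
class TerminalPath:
    state: PathState
    probability: float


# ---------------------------------------------------------------------------
# Generic chance-tree machinery


@dataclass(frozen=True)
class Leaf:
    payload: object


@dataclass(frozen=True)
class ChanceNode:
    branches: tuple  # of (probability, node) pairs

    def __post_init__(self) -> None:
        if not self.branches:
            raise TreeError("chance node with no branches")
        total = 0.0
        for p, _node in self.branches:
            if p < -1e-12 or p > 1.0 + 1e-12:
                raise TreeError(f"branch probability {p} outside [0, 1]")
            total += p
        if abs(total - 1.0) > 1e-9:
            raise TreeError(f"branch probabilities sum to {total!r}, expected 1")


Node = object  # Leaf | ChanceNode


def walk_paths(node: Node) -> list[tuple[float, object]]:
    """Brute-force enumeration of (probability, payload) over terminal paths."""
    out: list[tuple[float, object]] = []

    def _walk(n: Node, prob: float) -> None:
        if isinstance(n, Leaf):
            out.append((prob, n.payload))
        else:
            for p, child in n.branches:
                _walk(child, prob * p)

    _walk(node, 1.0)
    return out


def rollback(node: Node, payoff: Callable[[object], tuple]) -> tuple:
    """Expected payoff by recursive averaging (the rollback of the tree).

    ``payoff`` maps a leaf payload to a tuple of numbers; the expectation is
    component-wise.  Must agree exactly with the probability-weighted sum over
    ``walk_paths`` — the enumeration is the oracle for this shortcut.
    """
    if isinstance(node, Leaf):
        return tuple(payoff(node.payload))
    acc = None
    for p, child in node.branches:
        vals = rollback(child, payoff)
        if acc is None:
            acc = [p * v for v in vals]
        else:
            for i, v in enumerate(vals):
                acc[i] += p * v
    return tuple(acc)


# ---------------------------------------------------------------------------
# Epidemiology


def odds_ratio_to_probability(p0: float, or_value: float) -> float:
    """Event probability in the exposed group from baseline risk and odds ratio.

    Converts on the odds scale: odds1 = OR · p0/(1−p0), then back to a
    probability, i.e. ``OR·p0 / (1 − p0 + OR·p0)``.  Strictly increasing in
    both arguments; degenerate baselines (p0 of exactly 0 or 1) are returned
    unchanged.
    """
    if not (0.0 <= p0 <= 1.0):
        raise TreeError(f"baseline probability {p0} outside [0, 1]")
    if or_value <= 0.0:
        raise TreeError(f"odds ratio must be > 0, got {or_value}")
    if p0 in (0.0, 1.0):
        return p0
    return or_value * p0 / (1.0 - p0 + or_value * p0)


def effective_exposure(state: PathState) -> Regimen:
    """Year-long drug exposure implied by a terminal state.

    Usual care, appropriate use and rejected recommendations stay on
    standard-dose PPI.  Rebound after any deprescribing action reinstates the
    standard-dose regimen (mean rebound onset is short relative to the year,
    so reinstated patients carry full-dose risk).  Without rebound, dose
    reduction carries low-dose risk while discontinuation and switch to H2RA
    carry the non-user baseline risk.
    """
    if state.rebound:
        return Regimen.ppi_reinstated
    if state.triage is Triage.discontinued:
        return Regimen.none
    if state.triage is Triage.dose_reduced:
        return Regimen.ppi_low
    if state.triage is Triage.switched:
        return Regimen.h2ra
    return Regimen.ppi_standard


def interim_regimen(triage: Triage) -> Regimen:
    """Regimen held between a deprescribing action and reinstatement."""
    if triage is Triage.discontinued:
        return Regimen.none
    if triage is Triage.dose_reduced:
        return Regimen.ppi_low
    if triage is Triage.switched:
        return Regimen.h2ra
    raise TreeError(f"no interim regimen for triage {triage}")


def adverse_event_probabilities(
    realized: Mapping[str, float], regimen: Regimen
) -> dict[AdverseEvent, float]:
    """Yearly probabilities of the three adverse events for a regimen."""
    if regimen in (Regimen.ppi_standard, Regimen.ppi_reinstated):
        ors = ("or_ppi_hypomag", "or_ppi_pneumonia", "or_ppi_cdi")
    elif regimen is Regimen.ppi_low:
        ors = ("or_lowppi_hypomag", "or_lowppi_pneumonia", "or_lowppi_cdi")
    else:  # discontinued or switched to H2RA: baseline (non-user) risk
        ors = (None, None, None)
    base = ("p0_hypomag", "p0_pneumonia", "p0_cdi")
    events = (AdverseEvent.hypomagnesemia, AdverseEvent.pneumonia, AdverseEvent.cdi)
    out = {}
    for event, p0_name, or_name in zip(events, base, ors):
        p0 = realized[p0_name]
        out[event] = p0 if or_name is None else odds_ratio_to_probability(
            p0, realized[or_name]
        )
    return out


# ---------------------------------------------------------------------------
# Model construction


def _ae_subtree(
    realized: Mapping[str, float],
    strategy: Strategy,
    triage: Triage,
    rebound: bool,
) -> ChanceNode:
    """Adverse-event branches hanging off one exposure state."""
    state = PathState(strategy, triage, rebound, AdverseEvent.none,
                      AESetting.not_applicable, died=False)
    regimen = effective_exposure(state)
    probs = adverse_event_probabilities(realized, regimen)
    total = sum(probs.values())
    if total >= 1.0:
        raise TreeError(
            f"adverse-event probabilities sum to {total:.4f} >= 1 for regimen "
            f"{regimen.value}; cannot form the no-event branch"
        )

    def leaf(event: AdverseEvent, setting: AESetting, died: bool) -> Leaf:
        return Leaf(PathState(strategy, triage, rebound, event, setting, died))

    p_hosp_h = realized["p_hosp_hypomag"]
    p_hosp_p = realized["p_hosp_pneumonia"]
    p_mort_p = realized["p_mort_pneumonia"]
    p_mort_c = realized["p_mort_cdi"]

    hypomag = ChanceNode((
        (1.0 - p_hosp_h, leaf(AdverseEvent.hypomagnesemia, AESetting.outpatient, False)),
        (p_hosp_h, leaf(AdverseEvent.hypomagnesemia, AESetting.hospitalized, False)),
    ))
    pneumonia = ChanceNode((
        (1.0 - p_hosp_p, leaf(AdverseEvent.pneumonia, AESetting.outpatient, False)),
        (p_hosp_p, ChanceNode((
            (1.0 - p_mort_p, leaf(AdverseEvent.pneumonia, AESetting.hospitalized, False)),
            (p_mort_p, leaf(AdverseEvent.pneumonia, AESetting.hospitalized, True)),
        ))),
    ))
    cdi = ChanceNode((
        (1.0 - p_mort_c, leaf(AdverseEvent.cdi, AESetting.hospitalized, False)),
        (p_mort_c, leaf(AdverseEvent.cdi, AESetting.hospitalized, True)),
    ))
    return ChanceNode((
        (1.0 - total, leaf(AdverseEvent.none, AESetting.not_applicable, False)),
        (probs[AdverseEvent.hypomagnesemia], hypomag),
        (probs[AdverseEvent.pneumonia], pneumonia),
        (probs[AdverseEvent.cdi], cdi),
    ))


def build_strategy_tree(strategy: Strategy, realized: Mapping[str, float]) -> Node:
    """Chance tree for one strategy at one parameter realisation.

    The recommendation mix is renormalised to sum to 1 here, so that sampled,
    perturbed and one-way excursions of a single mix component remain valid
    probability trees.
    """
    if strategy is Strategy.usual_care:
        return _ae_subtree(realized, strategy, Triage.appropriate, rebound=False)

    p_inapp = realized["p_inappropriate"]
    mix = [realized["p_rec_discontinue"], realized["p_rec_dosedown"],
           realized["p_rec_switch"]]
    mix_total = sum(mix)
    if mix_total <= 0:
        raise TreeError("recommendation mix sums to zero")
    mix = [m / mix_total for m in mix]

    def action(triage: Triage, p_accept: float, p_rebound: float) -> ChanceNode:
        accepted = ChanceNode((
            (p_rebound, _ae_subtree(realized, strategy, triage, rebound=True)),
            (1.0 - p_rebound, _ae_subtree(realized, strategy, triage, rebound=False)),
        ))
        rejected = _ae_subtree(
            realized, strategy, Triage.inappropriate_not_accepted, rebound=False
        )
        return ChanceNode(((p_accept, accepted), (1.0 - p_accept, rejected)))

    inappropriate = ChanceNode((
        (mix[0], action(Triage.discontinued,
                        realized["p_accept_discontinue"],
                        realized["p_rebound_discontinue"])),
        (mix[1], action(Triage.dose_reduced,
                        realized["p_accept_dosedown"],
                        realized["p_rebound_dosedown"])),
        (mix[2], action(Triage.switched,
                        realized["p_accept_switch"],
                        realized["p_rebound_switch"])),
    ))
    return ChanceNode((
        (1.0 - p_inapp, _ae_subtree(realized, strategy, Triage.appropriate, False)),
        (p_inapp, inappropriate),
    ))


def strategy_paths(
    strategy: Strategy, realized: Mapping[str, float]
) -> list[TerminalPath]:
    """All terminal paths of one strategy, with probabilities summing to 1."""
    root = build_strategy_tree(strategy, realized)
    return [TerminalPath(state, p) for p, state in walk_paths(root)]
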