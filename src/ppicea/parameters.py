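"""Model parameters: loading, validation, distribution fitting and sampling.

The model is entirely configuration-driven.  A configuration file (YAML)
declares every clinical, utility and cost input as a ``ParameterValue`` —
base-case value, sensitivity range and distribution family — plus a block of
run constants (discount rate, willingness-to-pay threshold, rebound-onset
time, pharmacist working time, and an age → remaining-life-expectancy table).

The bundled default configuration (``data/table1_defaults.yaml``) encodes the
published input set for pharmacist-led PPI deprescribing versus usual care in
older ambulatory patients, evaluated from a public-healthcare-provider
perspective over a one-year horizon.

Distribution calibration: the configuration gives only a base value, a range
and a family.  The range is treated as an approximate central 95% interval,
so beta and gamma parameters are moment-matched to mean = base and
sd = (high − low)/(2·1.96); triangular distributions use (low, base, high)
directly as (min, mode, max).  The sd multiplier is exposed as ``sd_scale``.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterValue",
    "DistributionSpec",
    "RunSettings",
    "ModelParameters",
    "ParameterError",
    "load_parameters",
    "default_config_path",
    "fit_distribution",
    "sample_parameters",
    "PARAMETER_SCHEMA",
    "RECOMMENDATION_MIX",
]


class ParameterError(ValueError):
    """A named, human-readable configuration or validation failure."""


# ---------------------------------------------------------------------------
# Schema: every required parameter, its config section and its support.
# Kinds drive support validation:
#   probability / utility / decrement -> [0, 1]
#   ratio / cost / duration / count / years / minutes -> >= 0
_SECTION = str
_KIND = str

PARAMETER_SCHEMA: dict[str, tuple[_SECTION, _KIND]] = {
    # clinical
    "p_inappropriate": ("clinical", "probability"),
    "p_rec_discontinue": ("clinical", "probability"),
    "p_rec_dosedown": ("clinical", "probability"),
    "p_rec_switch": ("clinical", "probability"),
    "p_accept_discontinue": ("clinical", "probability"),
    "p_accept_dosedown": ("clinical", "probability"),
    "p_accept_switch": ("clinical", "probability"),
    "p_rebound_discontinue": ("clinical", "probability"),
    "p_rebound_dosedown": ("clinical", "probability"),
    "p_rebound_switch": ("clinical", "probability"),
    "p0_hypomag": ("clinical", "probability"),
    "p0_pneumonia": ("clinical", "probability"),
    "p0_cdi": ("clinical", "probability"),
    "or_ppi_hypomag": ("clinical", "ratio"),
    "or_ppi_pneumonia": ("clinical", "ratio"),
    "or_ppi_cdi": ("clinical", "ratio"),
    "or_lowppi_hypomag": ("clinical", "ratio"),
    "or_lowppi_pneumonia": ("clinical", "ratio"),
    "or_lowppi_cdi": ("clinical", "ratio"),
    "p_hosp_hypomag": ("clinical", "probability"),
    "p_hosp_pneumonia": ("clinical", "probability"),
    "p_mort_cdi": ("clinical", "probability"),
    "p_mort_pneumonia": ("clinical", "probability"),
    # utility
    "age_years": ("utility", "years"),
    "utility_age65plus": ("utility", "utility"),
    "disutil_relapse_on_meds": ("utility", "decrement"),
    "disutil_relapse_off_meds": ("utility", "decrement"),
    "disutil_hosp_hypomag": ("utility", "decrement"),
    "disutil_hosp_pneumonia": ("utility", "decrement"),
    "disutil_amb_pneumonia": ("utility", "decrement"),
    "disutil_cdi": ("utility", "decrement"),
    "los_hypomag_days": ("utility", "duration"),
    "los_pneumonia_days": ("utility", "duration"),
    "los_cdi_days": ("utility", "duration"),
    "convalescence_pneumonia_days": ("utility", "duration"),
    "outpatient_pneumonia_days": ("utility", "duration"),
    # cost
    "cost_ppi_standard_monthly": ("cost", "cost"),
    "cost_ppi_low_monthly": ("cost", "cost"),
    "cost_h2ra_monthly": ("cost", "cost"),
    "cost_hosp_per_day": ("cost", "cost"),
    "cost_clinic_visit": ("cost", "cost"),
    "n_clinic_visits_pneumonia": ("cost", "count"),
    "pharmacist_salary_monthly": ("cost", "cost"),
    "deprescribe_minutes_per_case": ("cost", "minutes"),
}

#: The three recommendation-mix components; they must sum to 1 at base case
#: and sampled draws are renormalised jointly.
RECOMMENDATION_MIX = ("p_rec_discontinue", "p_rec_dosedown", "p_rec_switch")

_UNIT_INTERVAL_KINDS = frozenset({"probability", "utility", "decrement"})
_FAMILIES = frozenset({"beta", "gamma", "triangular", "fixed"})


@dataclass(frozen=True)
class ParameterValue:
    """One model input: base value, sensitivity range, distribution family."""

    name: str
    base: float
    low: float | None = None
    high: float | None = None
    distribution: str = "fixed"

    def __post_init__(self) -> None:
        if self.distribution not in _FAMILIES:
            raise ParameterError(
                f"{self.name}: unknown distribution {self.distribution!r} "
                f"(expected one of {sorted(_FAMILIES)})"
            )
        has_range = self.low is not None or self.high is not None
        if has_range and (self.low is None or self.high is None):
            raise ParameterError(f"{self.name}: both low and high must be given")
        if self.distribution == "fixed":
            if has_range:
                raise ParameterError(
                    f"{self.name}: fixed parameters must not carry a range"
                )
        else:
            if not has_range:
                raise ParameterError(
                    f"{self.name}: distribution {self.distribution!r} requires "
                    "a (low, high) range; omit the range for fixed parameters"
                )
            if not (self.low <= self.base <= self.high):
                raise ParameterError(
                    f"{self.name}: range must satisfy low <= base <= high, got "
                    f"low={self.low}, base={self.base}, high={self.high}"
                )
        kind = PARAMETER_SCHEMA.get(self.name, (None, "ratio"))[1]
        bounds = (self.base,) if not has_range else (self.low, self.base, self.high)
        for value in bounds:
            if kind in _UNIT_INTERVAL_KINDS:
                if not (0.0 <= value <= 1.0):
                    raise ParameterError(
                        f"{self.name}: {kind} values must lie in [0, 1], got {value}"
                    )
            elif value < 0.0:
                raise ParameterError(
                    f"{self.name}: {kind} values must be >= 0, got {value}"
                )

    @property
    def is_fixed(self) -> bool:
        return self.distribution == "fixed"


@dataclass(frozen=True)
class DistributionSpec:
    """A fitted sampling distribution for one parameter.

    ``family`` is one of ``beta`` (args = α, β), ``gamma`` (args = shape k,
    scale θ), ``triangular`` (args = min, mode, max) or ``degenerate``
    (args = value,).
    """

    family: str
    args: tuple[float, ...]

    def mean(self) -> float:
        if self.family == "degenerate":
            return self.args[0]
        if self.family == "beta":
            a, b = self.args
            return a / (a + b)
        if self.family == "gamma":
            k, theta = self.args
            return k * theta
        if self.family == "triangular":
            lo, mode, hi = self.args
            return (lo + mode + hi) / 3.0
        raise ParameterError(f"unknown family {self.family!r}")

    def var(self) -> float:
        if self.family == "degenerate":
            return 0.0
        if self.family == "beta":
            a, b = self.args
            return a * b / ((a + b) ** 2 * (a + b + 1.0))
        if self.family == "gamma":
            k, theta = self.args
            return k * theta**2
        if self.family == "triangular":
            lo, mode, hi = self.args
            return (lo**2 + mode**2 + hi**2 - lo * mode - lo * hi - mode * hi) / 18.0
        raise ParameterError(f"unknown family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.family == "degenerate":
            value = self.args[0]
            return value if size is None else np.full(size, value)
        if self.family == "beta":
            return rng.beta(*self.args, size=size)
        if self.family == "gamma":
            k, theta = self.args
            return rng.gamma(k, theta, size=size)
        if self.family == "triangular":
            lo, mode, hi = self.args
            if lo == hi:
                return lo if size is None else np.full(size, lo)
            return rng.triangular(lo, mode, hi, size=size)
        raise ParameterError(f"unknown family {self.family!r}")


@dataclass
class RunSettings:
    """Run constants that are not sampled in sensitivity analyses."""

    discount_rate_annual: float = 0.03
    wtp_threshold_usd: float = 49023.0
    rebound_onset_days: float = 20.0
    pharmacist_working_minutes_per_month: float = 10560.0
    remaining_life_expectancy_years: float | None = None
    life_table: dict[float, float] | None = None

    def __post_init__(self) -> None:
        if self.discount_rate_annual < 0:
            raise ParameterError("discount_rate_annual must be >= 0")
        if self.wtp_threshold_usd < 0:
            raise ParameterError("wtp_threshold_usd must be >= 0")
        if self.rebound_onset_days < 0:
            raise ParameterError("rebound_onset_days must be >= 0")
        if self.pharmacist_working_minutes_per_month <= 0:
            raise ParameterError("pharmacist_working_minutes_per_month must be > 0")
        if self.remaining_life_expectancy_years is None and not self.life_table:
            raise ParameterError(
                "missing parameter: either remaining_life_expectancy_years or a "
                "life_table (age -> remaining years) is required in the run block"
            )
        if self.life_table:
            self.life_table = {float(a): float(e) for a, e in self.life_table.items()}
            for age, years in self.life_table.items():
                if years < 0:
                    raise ParameterError(
                        f"life_table: remaining years at age {age} must be >= 0"
                    )

    def life_expectancy(self, age_years: float) -> float:
        """Remaining life expectancy at ``age_years``.

        Uses the scalar override when configured, otherwise linear
        interpolation in the age → years life table (clamped at the ends).
        """
        if self.remaining_life_expectancy_years is not None:
            return float(self.remaining_life_expectancy_years)
        ages = np.array(sorted(self.life_table), dtype=float)
        years = np.array([self.life_table[a] for a in ages], dtype=float)
        return float(np.interp(age_years, ages, years))

    def to_dict(self) -> dict:
        out: dict = {
            "discount_rate_annual": self.discount_rate_annual,
            "wtp_threshold_usd": self.wtp_threshold_usd,
            "rebound_onset_days": self.rebound_onset_days,
            "pharmacist_working_minutes_per_month": self.pharmacist_working_minutes_per_month,
        }
        if self.remaining_life_expectancy_years is not None:
            out["remaining_life_expectancy_years"] = self.remaining_life_expectancy_years
        if self.life_table:
            out["life_table"] = dict(sorted(self.life_table.items()))
        return out


_REC_MIX_TOL = 1e-9


@dataclass
class ModelParameters:
    """The complete, validated set of model inputs plus run constants."""

    values: dict[str, ParameterValue]
    run: RunSettings = field(default_factory=RunSettings)

    def __post_init__(self) -> None:
        self.validate()

    # -- mapping-style access -------------------------------------------------
    def __getitem__(self, name: str) -> ParameterValue:
        try:
            return self.values[name]
        except KeyError:
            raise ParameterError(f"missing parameter: {name}") from None

    def __iter__(self) -> Iterator[ParameterValue]:
        return iter(self.values.values())

    def base_map(self) -> dict[str, float]:
        """Base-case realisation: every parameter at its base value."""
        return {name: pv.base for name, pv in self.values.items()}

    def validate(self) -> None:
        missing = [n for n in PARAMETER_SCHEMA if n not in self.values]
        if missing:
            raise ParameterError(f"missing parameter: {missing[0]}")
        unknown = [n for n in self.values if n not in PARAMETER_SCHEMA]
        if unknown:
            raise ParameterError(f"unknown parameter: {unknown[0]}")
        mix = sum(self.values[n].base for n in RECOMMENDATION_MIX)
        if abs(mix - 1.0) > _REC_MIX_TOL:
            raise ParameterError(
                "recommendation mix (p_rec_discontinue + p_rec_dosedown + "
                f"p_rec_switch) must sum to 1, got {mix!r}"
            )

    # -- transformations ------------------------------------------------------
    def with_value(self, name: str, base: float) -> "ModelParameters":
        """Copy with one parameter's base value replaced (range untouched).

        Used by one-way sensitivity analysis; bypasses the low <= base <= high
        ordering check but keeps support validation, since a one-way excursion
        sets base to an endpoint of the range.
        """
        pv = self[name]
        values = dict(self.values)
        values[name] = replace(pv, base=base, low=None, high=None, distribution="fixed") \
            if pv.is_fixed else replace(pv, base=base, low=min(pv.low, base), high=max(pv.high, base))
        out = copy.copy(self)
        out.values = values
        return out

    def with_all_fixed(self) -> "ModelParameters":
        """Copy with every distribution degenerate at its base value."""
        values = {
            name: ParameterValue(name=name, base=pv.base)
            for name, pv in self.values.items()
        }
        out = copy.copy(self)
        out.values = values
        return out

    def to_config(self) -> dict:
        """Serialise back to the configuration-dictionary layout."""
        out: dict = {"clinical": {}, "utility": {}, "cost": {}}
        for name, pv in self.values.items():
            section = PARAMETER_SCHEMA[name][0]
            entry: dict = {"base": pv.base}
            if not pv.is_fixed:
                entry.update(low=pv.low, high=pv.high, dist=pv.distribution)
            out[section][name] = entry
        out["run"] = self.run.to_dict()
        return out


# ---------------------------------------------------------------------------
# Loading


def default_config_path():
    """Path to the bundled default configuration file."""
    return resources.files("ppicea").joinpath("data/table1_defaults.yaml")


def load_parameters(config_path=None) -> ModelParameters:
    """Load and validate a model configuration.

    Parameters
    ----------
    config_path
        Path to a YAML configuration with sections ``clinical``, ``utility``,
        ``cost`` and ``run``.  ``None`` loads the bundled defaults.

    Raises
    ------
    ParameterError
        On a missing or unknown parameter, an out-of-support value, or a
        violated structural invariant; the message names the parameter and
        the rule.
    """
    if config_path is None:
        text = default_config_path().read_text()
    else:
        with open(config_path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ParameterError("configuration must be a mapping of sections")

    known_sections = {"clinical", "utility", "cost", "run"}
    unknown = set(raw) - known_sections
    if unknown:
        raise ParameterError(f"unknown section: {sorted(unknown)[0]}")

    values: dict[str, ParameterValue] = {}
    for section in ("clinical", "utility", "cost"):
        entries = raw.get(section, {}) or {}
        for name, entry in entries.items():
            if name not in PARAMETER_SCHEMA:
                raise ParameterError(f"unknown parameter: {name}")
            if PARAMETER_SCHEMA[name][0] != section:
                raise ParameterError(
                    f"{name}: belongs in section {PARAMETER_SCHEMA[name][0]!r}, "
                    f"found in {section!r}"
                )
            if isinstance(entry, (int, float)):
                entry = {"base": float(entry)}
            if not isinstance(entry, dict) or "base" not in entry:
                raise ParameterError(f"{name}: expected a mapping with a 'base' key")
            extra = set(entry) - {"base", "low", "high", "dist"}
            if extra:
                raise ParameterError(f"{name}: unknown key {sorted(extra)[0]!r}")
            values[name] = ParameterValue(
                name=name,
                base=float(entry["base"]),
                low=None if entry.get("low") is None else float(entry["low"]),
                high=None if entry.get("high") is None else float(entry["high"]),
                distribution=entry.get("dist", "fixed"),
            )

    run_raw = dict(raw.get("run", {}) or {})
    allowed_run = {
        "discount_rate_annual",
        "wtp_threshold_usd",
        "rebound_onset_days",
        "pharmacist_working_minutes_per_month",
        "remaining_life_expectancy_years",
        "life_table",
    }
    unknown_run = set(run_raw) - allowed_run
    if unknown_run:
        raise ParameterError(f"unknown run setting: {sorted(unknown_run)[0]}")
    run = RunSettings(**run_raw)
    return ModelParameters(values=values, run=run)


# ---------------------------------------------------------------------------
# Distribution fitting and sampling


def fit_distribution(pv: ParameterValue, sd_scale: float = 1.0) -> DistributionSpec:
    """Fit the sampling distribution for one parameter.

    Fixed parameters yield a degenerate distribution at the base value.
    Triangular uses (low, base, high) as (min, mode, max).  Beta and gamma
    are moment-matched with mean = base and sd = (high − low)/(2·1.96)·sd_scale.
    """
    if pv.is_fixed:
        return DistributionSpec("degenerate", (pv.base,))
    if pv.high == pv.low:
        warnings.warn(
            f"{pv.name}: zero-width range with {pv.distribution!r} distribution; "
            "treating as degenerate",
            stacklevel=2,
        )
        return DistributionSpec("degenerate", (pv.base,))
    if pv.distribution == "triangular":
        return DistributionSpec("triangular", (pv.low, pv.base, pv.high))

    m = pv.base
    sd = (pv.high - pv.low) / (2.0 * 1.96) * sd_scale
    v = sd * sd
    if pv.distribution == "beta":
        if not (0.0 < m < 1.0):
            raise ParameterError(
                f"{pv.name}: beta distribution requires base in (0, 1), got {m}"
            )
        if v >= m * (1.0 - m):
            raise ParameterError(
                f"{pv.name}: range too wide for a beta with mean {m}; "
                "variance must be below m(1-m)"
            )
        nu = m * (1.0 - m) / v - 1.0
        return DistributionSpec("beta", (m * nu, (1.0 - m) * nu))
    if pv.distribution == "gamma":
        if m <= 0.0:
            raise ParameterError(
                f"{pv.name}: gamma distribution requires base > 0, got {m}"
            )
        return DistributionSpec("gamma", (m * m / v, v / m))
    raise ParameterError(f"{pv.name}: cannot fit family {pv.distribution!r}")


def fit_all(params: ModelParameters, sd_scale: float = 1.0) -> dict[str, DistributionSpec]:
    """Fitted ``DistributionSpec`` for every parameter, in schema order."""
    return {name: fit_distribution(params[name], sd_scale) for name in PARAMETER_SCHEMA}


def sample_parameters(
    params: ModelParameters,
    rng: int | np.random.Generator,
    specs: Mapping[str, DistributionSpec] | None = None,
) -> dict[str, float]:
    """One joint independent draw of all parameters.

    Fixed parameters are returned at their base value.  The three
    recommendation-mix probabilities are drawn from their individual beta
    distributions and renormalised to sum to 1.  Reproducible for a given
    integer seed (or supplied ``numpy.random.Generator`` state).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if specs is None:
        specs = fit_all(params)
    draw = {name: float(specs[name].sample(rng)) for name in PARAMETER_SCHEMA}
    total = sum(draw[n] for n in RECOMMENDATION_MIX)
    if total > 0:
        for n in RECOMMENDATION_MIX:
            draw[n] /= total
    return draw
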