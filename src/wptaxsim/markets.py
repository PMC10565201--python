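"""Domain types for a multi-segment tobacco market and config-file readers.

A *market* is a small set of segments (here defined by flavour and smoking
location) each carrying its consumption share, retail price of one 20 g unit,
own-price elasticity of demand, and the tax rules that apply to it: an import
duty levied on the CIF/ex-factory price, an ad valorem excise levied on
CIF + duty, and a per-unit specific excise (zero at baseline in markets that
have none).  All monetary amounts are USD per 20 g unit.

Configuration files are plain YAML; :func:`load_market` validates every
invariant and raises :class:`MarketValidationError` naming the offending field
and segment.  Two packaged parameter sets are exposed through
:func:`egypt_market` (the four-segment Egyptian market, 2022 tax law) and
:func:`who_single_share_market` (the single "premium home" share underlying
the WHO global-report tax-structure figures).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "MarketSegment",
    "Market",
    "ConsumptionInputs",
    "MortalityAssumptions",
    "AdjustmentFactors",
    "MarketValidationError",
    "load_market",
    "write_market",
    "load_consumption",
    "load_mortality",
    "load_adjustment",
    "inflation_factor",
    "convert_currency",
    "egypt_market",
    "egypt_consumption",
    "egypt_mortality",
    "egypt_adjustment",
    "who_single_share_market",
    "who_secondary_mortality",
]

SHARE_TOL = 1e-6
#: Days per calendar year used to annualise daily consumption.
DAYS_PER_YEAR = 365.25


class MarketValidationError(ValueError):
    """A market description violates a structural invariant."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise MarketValidationError(message)


@dataclass(frozen=True)
class MarketSegment:
    """One market segment: its price, demand elasticity and tax rules.

    Parameters
    ----------
    name :
        Segment label, e.g. ``"cafe_flavoured"``.
    share :
        Fraction of baseline consumption attributed to the segment, in [0, 1].
    base_price :
        Baseline retail price of one 20 g unit (USD).
    elasticity :
        Own-price elasticity of demand; must be negative.
    cif :
        CIF (imported) or ex-factory (domestic) price per unit (USD).
    duty_rate :
        Import duty as a fraction of the CIF price.
    advalorem_rate :
        Ad valorem excise as a fraction of (CIF + duty amount).
    specific :
        Baseline specific excise per unit (USD); zero where none applies.
    """

    name: str
    share: float
    base_price: float
    elasticity: float
    cif: float
    duty_rate: float = 0.0
    advalorem_rate: float = 0.0
    specific: float = 0.0

    def __post_init__(self) -> None:
        n = self.name
        _require(bool(n), "segment name must be non-empty")
        _require(0.0 <= self.share <= 1.0, f"segment {n!r}: share must be in [0, 1]")
        _require(self.base_price > 0.0, f"segment {n!r}: base_price must be positive")
        _require(self.elasticity < 0.0,
                 f"segment {n!r}: elasticity must be negative (got {self.elasticity}); "
                 "magnitude tables must be loaded with elasticities_are_magnitudes=true")
        _require(self.cif >= 0.0, f"segment {n!r}: cif must be non-negative")
        _require(self.duty_rate >= 0.0, f"segment {n!r}: duty_rate must be non-negative")
        _require(self.advalorem_rate >= 0.0,
                 f"segment {n!r}: advalorem_rate must be non-negative")
        _require(self.specific >= 0.0, f"segment {n!r}: specific must be non-negative")
        # Non-negative industry margin at baseline: the price must cover the
        # CIF cost plus every tax levied on it.
        duty = self.duty_rate * self.cif
        advalorem = self.advalorem_rate * (self.cif + duty)
        total = self.cif + duty + self.specific + advalorem
        _require(
            total <= self.base_price + 1e-9,
            f"segment {n!r}: cif + taxes ({total:.6f}) exceed base_price "
            f"({self.base_price:.6f}); baseline margin would be negative",
        )


@dataclass(frozen=True)
class Market:
    """An ordered collection of segments plus the calibrated annual volume.

    ``base_quantity`` is the calibrated total annual consumption in 20 g
    units; each segment's baseline quantity is ``share * base_quantity``.
    """

    segments: tuple[MarketSegment, ...]
    base_quantity: float
    name: str = "market"

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        _require(len(self.segments) > 0, "market must contain at least one segment")
        _require(self.base_quantity > 0.0, "base_quantity must be positive")
        names = [s.name for s in self.segments]
        _require(len(set(names)) == len(names),
                 f"segment names must be unique (got {names})")
        total = sum(s.share for s in self.segments)
        _require(abs(total - 1.0) <= SHARE_TOL,
                 f"segment shares must sum to 1 (got {total:.8f})")

    @property
    def segment_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments)

    def baseline_quantities(self) -> list[float]:
        """Per-segment baseline annual 20 g units, ``share * base_quantity``."""
        return [s.share * self.base_quantity for s in self.segments]

    def replace_segment(self, name: str, **changes) -> "Market":
        """Return a copy of the market with one segment's fields replaced."""
        if name not in self.segment_names:
            raise KeyError(f"no segment named {name!r}")
        segs = tuple(
            dataclasses.replace(s, **changes) if s.name == name else s
            for s in self.segments
        )
        return dataclasses.replace(self, segments=segs)


@dataclass(frozen=True)
class ConsumptionInputs:
    """Survey-derived consumption intensity used to build annual unit counts."""

    prevalence_daily: float
    units_per_session: float
    sessions_per_day: float
    population: float
    illicit_fraction: float = 0.0
    days_per_year: float = DAYS_PER_YEAR

    def __post_init__(self) -> None:
        _require(0.0 <= self.prevalence_daily <= 1.0,
                 "prevalence_daily must be in [0, 1]")
        _require(0.0 <= self.illicit_fraction <= 1.0,
                 "illicit_fraction must be in [0, 1]")
        for f in ("units_per_session", "sessions_per_day", "population",
                  "days_per_year"):
            _require(getattr(self, f) >= 0.0, f"{f} must be non-negative")


@dataclass(frozen=True)
class MortalityAssumptions:
    """Assumptions converting consumption reductions into deaths averted.

    Half of any reduction in smoking is attributed to quitting rather than
    cutting down, and 35% of quitters are assumed to have otherwise died
    prematurely; ``smoker_base`` is the count of current smokers the
    per-segment relative reductions are scaled by.
    """

    smoker_base: float
    quit_fraction: float = 0.5
    mortality_fraction: float = 0.35

    def __post_init__(self) -> None:
        _require(0.0 <= self.quit_fraction <= 1.0, "quit_fraction must be in [0, 1]")
        _require(0.0 <= self.mortality_fraction <= 1.0,
                 "mortality_fraction must be in [0, 1]")
        _require(self.smoker_base > 0.0, "smoker_base must be positive")


@dataclass(frozen=True)
class AdjustmentFactors:
    """Inflation rates (per calendar year, as fractions) and the USD/EGP rate."""

    exchange_rate: float
    inflation_rates: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(self.exchange_rate > 0.0, "exchange_rate must be positive")
        for year, rate in self.inflation_rates.items():
            _require(rate > -1.0, f"inflation rate for {year} must exceed -1")


def inflation_factor(factors: AdjustmentFactors, from_year: int, to_year: int) -> float:
    """Cumulative price multiplier from ``from_year`` to ``to_year``.

    The factor is the product of ``1 + rate_y`` over the years in the
    half-open interval ``(from_year, to_year]``; every year in that interval
    must be present in the rate table.
    """
    if to_year < from_year:
        raise ValueError("to_year must not precede from_year")
    out = 1.0
    for year in range(from_year + 1, to_year + 1):
        if year not in factors.inflation_rates:
            raise KeyError(f"no inflation rate for year {year}")
        out *= 1.0 + factors.inflation_rates[year]
    return out


def convert_currency(amount_egp: float, factors: AdjustmentFactors) -> float:
    """Convert an EGP amount to USD at the table's exchange rate."""
    if amount_egp < 0.0:
        raise ValueError("amount must be non-negative")
    return amount_egp * factors.exchange_rate


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

_SEGMENT_FIELDS = ("name", "share", "base_price", "elasticity", "cif")


def _as_document(config) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    doc = yaml.safe_load(Path(config).read_text())
    if not isinstance(doc, Mapping):
        raise MarketValidationError("market config must be a YAML mapping")
    return dict(doc)


def load_market(config, *, elasticities_are_magnitudes: bool | None = None) -> Market:
    """Read and validate a market description.

    Parameters
    ----------
    config :
        A mapping or a path to a YAML file with keys ``segments`` (list of
        segment mappings) and ``base_quantity``.
    elasticities_are_magnitudes :
        Published tables often print elasticities as magnitudes.  Elasticities
        are stored signed (negative); positive values in a config are rejected
        unless this flag (or the document key of the same name) is true, in
        which case they are negated on load.
    """
    doc = _as_document(config)
    if elasticities_are_magnitudes is None:
        elasticities_are_magnitudes = bool(doc.get("elasticities_are_magnitudes", False))
    raw_segments = doc.get("segments")
    if not raw_segments:
        raise MarketValidationError("market config must list at least one segment")
    segments = []
    for i, raw in enumerate(raw_segments):
        missing = [f for f in _SEGMENT_FIELDS if f not in raw]
        if missing:
            label = raw.get("name", f"#{i}")
            raise MarketValidationError(
                f"segment {label!r}: missing field(s) {', '.join(missing)}")
        elasticity = float(raw["elasticity"])
        if elasticities_are_magnitudes and elasticity > 0:
            elasticity = -elasticity
        segments.append(MarketSegment(
            name=str(raw["name"]),
            share=float(raw["share"]),
            base_price=float(raw["base_price"]),
            elasticity=elasticity,
            cif=float(raw["cif"]),
            duty_rate=float(raw.get("duty_rate", 0.0)),
            advalorem_rate=float(raw.get("advalorem_rate", 0.0)),
            specific=float(raw.get("specific", 0.0)),
        ))
    if "base_quantity" not in doc:
        raise MarketValidationError("market config: missing field base_quantity")
    return Market(
        segments=tuple(segments),
        base_quantity=float(doc["base_quantity"]),
        name=str(doc.get("name", "market")),
    )


def write_market(market: Market, path) -> None:
    """Write a market back to YAML; ``load_market`` round-trips all fields."""
    doc = {
        "name": market.name,
        "base_quantity": market.base_quantity,
        "segments": [dataclasses.asdict(s) for s in market.segments],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_consumption(config) -> ConsumptionInputs:
    """Read the ``consumption`` section of a market config."""
    doc = _as_document(config)
    if "consumption" not in doc:
        raise MarketValidationError("config has no 'consumption' section")
    return ConsumptionInputs(**{k: float(v) for k, v in doc["consumption"].items()})


def load_mortality(config) -> MortalityAssumptions:
    """Read the ``mortality`` section of a market config.

    ``smoker_base`` may be given directly, or as ``prevalence_current``
    together with a top-level ``population_15plus`` count.
    """
    doc = _as_document(config)
    if "mortality" not in doc:
        raise MarketValidationError("config has no 'mortality' section")
    raw = dict(doc["mortality"])
    if "smoker_base" not in raw:
        prevalence = float(raw.pop("prevalence_current"))
        population = float(raw.pop("population", doc.get("population_15plus", 0.0)))
        raw["smoker_base"] = prevalence * population
    else:
        raw.pop("prevalence_current", None)
    return MortalityAssumptions(**{k: float(v) for k, v in raw.items()})


def load_adjustment(config) -> AdjustmentFactors:
    """Read the ``adjustment`` (inflation/exchange) section of a config."""
    doc = _as_document(config)
    if "adjustment" not in doc:
        raise MarketValidationError("config has no 'adjustment' section")
    raw = dict(doc["adjustment"])
    rates = {int(y): float(r) for y, r in raw.get("inflation_rates", {}).items()}
    return AdjustmentFactors(exchange_rate=float(raw["exchange_rate"]),
                             inflation_rates=rates)


# ---------------------------------------------------------------------------
# Packaged parameter sets
# ---------------------------------------------------------------------------

def _fixture(name: str) -> dict:
    text = resources.files("wptaxsim.data").joinpath(name).read_text()
    return yaml.safe_load(text)


def egypt_market() -> Market:
    """The four-segment Egyptian waterpipe tobacco market (2022 tax law)."""
    return load_market(_fixture("egypt.yaml"))


def egypt_consumption() -> ConsumptionInputs:
    return load_consumption(_fixture("egypt.yaml"))


def egypt_mortality() -> MortalityAssumptions:
    """Deaths-averted assumptions scaled by the 4.5% x 67.6M smoker base."""
    return load_mortality(_fixture("egypt.yaml"))


def egypt_adjustment() -> AdjustmentFactors:
    return load_adjustment(_fixture("egypt.yaml"))


def who_single_share_market() -> Market:
    """The single "premium home" share behind the WHO tax-structure figures."""
    return load_market(_fixture("who_single_share.yaml"))


def who_secondary_mortality() -> MortalityAssumptions:
    """Deaths assumptions for the single-share analysis.

    The smoker base here uses the World Bank population matched to the STEPS
    survey age range (60,409,575) rather than the >15-years census count used
    by the four-segment battery; see the methods note.
    """
    return load_mortality(_fixture("who_single_share.yaml"))
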