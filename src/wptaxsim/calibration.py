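"""Reconstruct annual consumption from survey inputs and calibrate it.

Annual consumption in 20 g units is the product of units smoked per session,
sessions per day, daily-use prevalence, the population count and days per
year.  The raw product is then calibrated by a single multiplicative factor
so that the base-scenario market matches an external anchor (here the
published calibrated base quantity, chosen so that baseline government
revenue matches official fiscal statements).
"""

from __future__ import annotations

from dataclasses import dataclass

from .markets import ConsumptionInputs

__all__ = ["CalibrationResult", "annual_units", "calibrate_to_base"]


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of scaling raw annual units to an external anchor."""

    raw_annual_units: float
    calibration_factor: float
    calibrated_units: float
    anchor: str

    def __post_init__(self) -> None:
        if self.calibration_factor <= 0:
            raise ValueError("calibration_factor must be positive")
        if abs(self.calibrated_units
               - self.calibration_factor * self.raw_annual_units) > 1e-6:
            raise ValueError("calibrated_units must equal factor * raw units")


def annual_units(inputs: ConsumptionInputs, population: float | None = None,
                 ) -> float:
    """Raw annual consumption in 20 g units implied by the survey inputs.

    ``units_per_session * sessions_per_day * prevalence_daily * population *
    days_per_year``.  ``population`` defaults to the one stored on the
    inputs.
    """
    if population is None:
        population = inputs.population
    if population < 0:
        raise ValueError("population must be non-negative")
    return (inputs.units_per_session * inputs.sessions_per_day
            * inputs.prevalence_daily * population * inputs.days_per_year)


def calibrate_to_base(raw: float, anchor_units: float,
                      anchor: str = "published base quantity",
                      ) -> CalibrationResult:
    """Single multiplicative factor mapping raw units onto the anchor.

    The factor is ``anchor_units / raw`` so the calibrated total equals the
    anchor exactly; it is applied to total units before the market-share
    split.
    """
    if raw <= 0 or anchor_units <= 0:
        raise ValueError("raw and anchor units must be positive")
    factor = anchor_units / raw
    return CalibrationResult(
        raw_annual_units=raw,
        calibration_factor=factor,
        calibrated_units=anchor_units,
        anchor=anchor,
    )
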