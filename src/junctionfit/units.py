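"""Time-unit tags and rate conversion.

Rates in this package always carry an explicit time-unit tag (``"s"`` or
``"min"``); published work on junction resolvases mixes s⁻¹ (single-turnover
strand cleavage) and min⁻¹ (plasmid cruciform time courses), so units are
never inferred silently.
"""

from .errors import UnitError

#: Recognized time-unit tags, with their length in seconds.
TIME_UNITS: dict[str, float] = {"s": 1.0, "min": 60.0, "h": 3600.0}


def check_time_unit(unit: str) -> str:
    """Validate a time-unit tag, returning it unchanged."""
    if unit not in TIME_UNITS:
        raise UnitError(
            f"unknown time unit {unit!r}; expected one of {sorted(TIME_UNITS)}"
        )
    return unit


def convert_rate(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a first-order rate constant between reciprocal time units.

    A rate of 0.008 s⁻¹ is ``convert_rate(0.008, "s", "min") == 0.48`` min⁻¹.
    """
    check_time_unit(from_unit)
    check_time_unit(to_unit)
    return value * TIME_UNITS[to_unit] / TIME_UNITS[from_unit]


def convert_time(value, from_unit: str, to_unit: str):
    """Convert a time (scalar or array) between units."""
    check_time_unit(from_unit)
    check_time_unit(to_unit)
    return value * TIME_UNITS[from_unit] / TIME_UNITS[to_unit]
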