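"""Time-unit conversions used across the package.

All clinical times are recorded relative to injury: admission delay and
blood-draw time in hours, infection onsets in fractional days. Every
conversion between the two goes through this module so the 24 appears in
exactly one place.
"""

HOURS_PER_DAY = 24.0


def days_to_hours(days: float) -> float:
    return days * HOURS_PER_DAY


def hours_to_days(hours: float) -> float:
    return hours / HOURS_PER_DAY
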