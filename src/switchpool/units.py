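"""Unit conventions.

All kinetic parameters and generator entries are rates per minute; all
reported times are in years.  Conversion happens only at the reporting
boundary, through the single constant below.
"""

#: Minutes per year, 365 days of 1440 minutes.
MINUTES_PER_YEAR = 365.0 * 1440.0  # = 525600


def per_minute_to_per_year(rate: float) -> float:
    return rate * MINUTES_PER_YEAR


def minutes_to_years(t: float) -> float:
    return t / MINUTES_PER_YEAR


def years_to_minutes(t: float) -> float:
    return t * MINUTES_PER_YEAR
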