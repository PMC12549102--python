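"""Maternal distress questionnaires: range validation and symptom flags.

Four self-report instruments are used: the Spielberger State and Trait
Anxiety Inventories (SSAI/STAI; 20 items each, scores 20-80), the Perceived
Stress Scale (PSS; 10 items, 0-40) and the Edinburgh Postnatal Depression
Scale (EPDS; 10 items, 0-30). Scores at or above the conventional screening
cutoffs (SSAI/STAI >= 40, PSS >= 15, EPDS >= 10) flag symptoms of anxiety,
stress and depression respectively; the flags are screening indicators, not
clinical diagnoses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from fetalcwas.exceptions import ScoreRangeError

#: instrument -> (min score, max score, symptom cutoff, flag name)
INSTRUMENTS: dict[str, tuple[float, float, float, str]] = {
    "ssai": (20.0, 80.0, 40.0, "state_anxiety"),
    "stai": (20.0, 80.0, 40.0, "trait_anxiety"),
    "pss": (0.0, 40.0, 15.0, "stress"),
    "epds": (0.0, 30.0, 10.0, "depression"),
}


@dataclass(frozen=True)
class DistressScores:
    """One participant's questionnaire scores; any score may be missing (None/NaN)."""

    ssai: float | None = None
    stai: float | None = None
    pss: float | None = None
    epds: float | None = None

    def get(self, instrument: str) -> float | None:
        return getattr(self, instrument)


def _is_missing(value: float | None) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def validate_scores(s: DistressScores) -> DistressScores:
    """Pass through scores that lie in their instrument's range.

    Missing values are allowed. An out-of-range score raises a
    :class:`ScoreRangeError` naming the offending instrument.
    """
    for instrument, (lo, hi, _cutoff, _flag) in INSTRUMENTS.items():
        value = s.get(instrument)
        if _is_missing(value):
            continue
        if not (lo <= value <= hi):
            raise ScoreRangeError(
                f"{instrument.upper()} score {value} outside the instrument "
                f"range [{lo:g}, {hi:g}]"
            )
    return s


def flag_symptoms(s: DistressScores) -> dict[str, bool | None]:
    """Screening flags at the standard inclusive cutoffs.

    Returns a dict keyed by symptom name (state_anxiety, trait_anxiety,
    stress, depression). A missing score yields a missing (None) flag rather
    than False.
    """
    flags: dict[str, bool | None] = {}
    for instrument, (_lo, _hi, cutoff, flag_name) in INSTRUMENTS.items():
        value = s.get(instrument)
        flags[flag_name] = None if _is_missing(value) else bool(value >= cutoff)
    return flags
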