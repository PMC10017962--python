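"""Acoustic biomarkers: contour variability and pause statistics.

Ten interpretable measures of hypokinetic dysarthria: pitch variability
(F0STD), first-formant variability (F1STD), loudness variability (INTSTD),
and seven pause/speech-time statistics derived from the speech/pause
segmentation (SPTIME, SILTIME, SILPERC, SILSPRAT, SILDUR, SILVAR).

Conventions: every named standard deviation is the sample SD (n-1 in the
denominator); SPTIME is net speech time in seconds; degenerate recordings
(no pauses) yield defined zeros rather than missing values so cohorts stay
rectangular — callers can flag them from the segmentation.
"""

from __future__ import annotations

import numpy as np

from .audio import Contour, Segmentation

__all__ = ["contour_std", "pause_features", "PAUSE_FEATURE_NAMES"]

PAUSE_FEATURE_NAMES = ("SPTIME", "SILTIME", "SILPERC", "SILSPRAT", "SILDUR", "SILVAR")


def contour_std(c: Contour) -> float:
    """Sample standard deviation over valid frames; NaN when < 2 frames."""
    v = c.valid_values
    if len(v) < 2:
        return float("nan")
    return float(np.std(v, ddof=1))


def pause_features(s: Segmentation) -> dict[str, float]:
    """Speech-time and pause statistics of a segmentation.

    SPTIME   total speech time (s)
    SILTIME  total pause time (s)
    SILPERC  100 * SILTIME / (SPTIME + SILTIME)
    SILSPRAT SILTIME / SPTIME
    SILDUR   mean pause duration (0 when no pauses)
    SILVAR   median absolute deviation of pause durations (0 when < 2 pauses)

    Raises ValueError when the segmentation contains no speech.
    """
    speech = s.durations("speech")
    pauses = s.durations("pause")
    if len(speech) == 0:
        raise ValueError("segmentation has no speech intervals")
    sptime = float(speech.sum())
    siltime = float(pauses.sum())
    total = sptime + siltime
    out = {
        "SPTIME": sptime,
        "SILTIME": siltime,
        "SILPERC": 100.0 * siltime / total,
        "SILSPRAT": siltime / sptime,
        "SILDUR": float(pauses.mean()) if len(pauses) else 0.0,
        "SILVAR": 0.0,
    }
    if len(pauses) >= 2:
        med = np.median(pauses)
        out["SILVAR"] = float(np.median(np.abs(pauses - med)))
    return out
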