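"""AGGRESCAN-style aggregation-propensity profiling.

Each residue carries an experimentally derived in-vivo aggregation-propensity
value (a4v); a sequence's profile is the per-residue lookup, smoothed by a
centred moving average (the hot-spot window average, HWA).  Maximal runs of
consecutive residues with HWA above a threshold are aggregation hot spots
(prolines are beta-breakers and may split a run).  The scalar summary used for
screening is the normalised a4v sum score::

    Na4vSS = 100 * a4vSS / N = 100 * mean(a4v)

i.e. the a4v sum rescaled per 100 residues.  The screening cascade excludes
peptides with Na4vSS strictly below -57, so a boundary value of exactly -57 is
retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._scales import A4V_SCALE
from .library import PeptideSeq, validate_sequence

__all__ = [
    "AggregationProfile",
    "a4v_profile",
    "windowed_average",
    "detect_hot_spots",
    "aggregation_summary",
    "passes_na4vss",
    "DEFAULT_WINDOW",
    "DEFAULT_HOTSPOT_THRESHOLD",
    "DEFAULT_MIN_RUN",
    "NA4VSS_CUTOFF",
]

DEFAULT_WINDOW = 5          # original method's short-sequence (<75 aa) window
MAX_WINDOW = 11
DEFAULT_HOTSPOT_THRESHOLD = -0.02   # hot-spot threshold of the original method
DEFAULT_MIN_RUN = 5
NA4VSS_CUTOFF = -57.0


def _as_str(seq: PeptideSeq | str) -> str:
    return seq.sequence if isinstance(seq, PeptideSeq) else validate_sequence(seq)


def a4v_profile(
    seq: PeptideSeq | str, scale: dict[str, float] | None = None
) -> np.ndarray:
    """Per-residue a4v values (elementwise scale lookup)."""
    sequence = _as_str(seq)
    table = A4V_SCALE if scale is None else scale
    try:
        return np.array([table[r] for r in sequence])
    except KeyError as exc:
        raise KeyError(f"a4v scale has no value for residue {exc.args[0]!r}") from exc


def windowed_average(profile: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centred moving average of the profile (the HWA).

    Windows are truncated at the termini rather than padded, so the HWA is
    defined at every position and a constant profile maps to itself.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > MAX_WINDOW:
        raise ValueError(f"window {window} exceeds maximum {MAX_WINDOW}")
    profile = np.asarray(profile, dtype=float)
    n = len(profile)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = profile[lo:hi].mean()
    return out


def detect_hot_spots(
    hwa: np.ndarray,
    seq: PeptideSeq | str,
    threshold: float = DEFAULT_HOTSPOT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    proline_breaks: bool = True,
) -> list[tuple[int, int, float]]:
    """Maximal runs of >= ``min_run`` consecutive residues with HWA > threshold.

    Returns (start, end, peak) intervals, 1-based inclusive, ordered and
    disjoint.  With ``proline_breaks`` a proline inside a supra-threshold run
    splits it (prolines are strong beta-sheet breakers), and each fragment
    must independently reach ``min_run``.
    """
    sequence = _as_str(seq)
    hwa = np.asarray(hwa, dtype=float)
    if len(hwa) != len(sequence):
        raise ValueError("HWA length must match sequence length")
    above = hwa > threshold
    if proline_breaks:
        above &= np.array([r != "P" for r in sequence])
    spots: list[tuple[int, int, float]] = []
    start = None
    for i, flag in enumerate(list(above) + [False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                peak = float(hwa[start:i].max())
                spots.append((start + 1, i, peak))
            start = None
    return spots


@dataclass(frozen=True)
class AggregationProfile:
    """Full aggregation profile of one peptide."""

    sequence: str
    a4v: np.ndarray
    window: int
    hwa: np.ndarray
    hot_spots: list[tuple[int, int, float]]
    a4v_ss: float      # plain sum of per-residue a4v
    na4v_ss: float     # a4v_ss normalised per 100 residues


def aggregation_summary(
    seq: PeptideSeq | str,
    scale: dict[str, float] | None = None,
    window: int = DEFAULT_WINDOW,
    threshold: float = DEFAULT_HOTSPOT_THRESHOLD,
    min_run: int = DEFAULT_MIN_RUN,
    proline_breaks: bool = True,
) -> AggregationProfile:
    """Profile, HWA, hot spots and the Na4vSS summary for one peptide."""
    sequence = _as_str(seq)
    profile = a4v_profile(sequence, scale)
    hwa = windowed_average(profile, window)
    spots = detect_hot_spots(hwa, sequence, threshold, min_run, proline_breaks)
    a4v_ss = float(profile.sum())
    return AggregationProfile(
        sequence=sequence,
        a4v=profile,
        window=window,
        hwa=hwa,
        hot_spots=spots,
        a4v_ss=a4v_ss,
        na4v_ss=100.0 * a4v_ss / len(sequence),
    )


def passes_na4vss(na4v_ss: float, cutoff: float = NA4VSS_CUTOFF) -> bool:
    """Screening predicate: excluded iff Na4vSS < cutoff (strictly).

    A peptide sitting exactly on the cutoff is retained.
    """
    return na4v_ss >= cutoff
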