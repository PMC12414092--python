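"""Per-peptide physicochemical descriptors.

Mass, integer net charge, isoelectric point, mean hydrophobicity, helical
hydrophobic moment (amphipathicity), and the AAC/DPC composition feature
vectors used by the toxicity model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _scales
from .library import PeptideSeq, validate_sequence

__all__ = [
    "FeatureVector",
    "molecular_weight",
    "net_charge",
    "isoelectric_point",
    "hydrophobicity_mean",
    "hydrophobic_moment",
    "composition_features",
    "AAC_ORDER",
    "DPC_ORDER",
]

AAC_ORDER: tuple[str, ...] = tuple(sorted(_scales.STANDARD_RESIDUES))
DPC_ORDER: tuple[str, ...] = tuple(
    a + b for a, b in itertools.product(AAC_ORDER, repeat=2)
)


def _as_str(seq: PeptideSeq | str) -> str:
    return seq.sequence if isinstance(seq, PeptideSeq) else validate_sequence(seq)


def molecular_weight(seq: PeptideSeq | str, mode: str = "average") -> float:
    """Peptide mass in Da: sum of residue masses plus one water.

    ``mode`` is ``"average"`` (default) or ``"monoisotopic"``.
    """
    sequence = _as_str(seq)
    if mode == "average":
        table, water = _scales.AVERAGE_RESIDUE_MASS, _scales.WATER_MASS_AVERAGE
    elif mode == "monoisotopic":
        table, water = (
            _scales.MONOISOTOPIC_RESIDUE_MASS,
            _scales.WATER_MASS_MONOISOTOPIC,
        )
    else:
        raise ValueError(f"unknown mass mode {mode!r}")
    # sum in integer 1e-5 Da units: exact, order-free, so residue swaps with
    # equal summed table masses (e.g. D+Q vs E+N) come out bit-identical
    scale = 10**5
    total = sum(round(table[r] * scale) for r in sequence) + round(water * scale)
    return total / scale


def net_charge(seq: PeptideSeq | str) -> int:
    """Integer formal charge at neutral pH: (#K + #R) - (#D + #E).

    Histidine and the termini contribute 0 in this convention, which matches
    the usual web-server "charge" column (e.g. every GEPDTYWQ-derived variant
    carries exactly two acidic positions and no basic ones, hence -2).
    """
    sequence = _as_str(seq)
    return (
        sequence.count("K") + sequence.count("R")
        - sequence.count("D") - sequence.count("E")
    )


def _hh_charge(sequence: str, ph: float, pka: dict[str, float]) -> float:
    """Henderson-Hasselbalch net charge of the peptide at a given pH."""
    positive = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    for res in ("K", "R", "H"):
        if res in pka:
            positive += sequence.count(res) / (1.0 + 10.0 ** (ph - pka[res]))
    negative = 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for res in ("D", "E", "C", "Y"):
        if res in pka:
            negative += sequence.count(res) / (1.0 + 10.0 ** (pka[res] - ph))
    return positive - negative


def isoelectric_point(
    seq: PeptideSeq | str, pka_set: str = "emboss", tol: float = 1e-4
) -> float:
    """pH at which the Henderson-Hasselbalch net charge is zero.

    The charge curve is strictly decreasing in pH, so the root on [0, 14] is
    unique; found by bisection (Brent) to ``tol``.
    """
    sequence = _as_str(seq)
    pka = _scales.PKA_SETS[pka_set]
    return float(
        brentq(lambda ph: _hh_charge(sequence, ph, pka), 0.0, 14.0, xtol=tol)
    )


def hydrophobicity_mean(
    seq: PeptideSeq | str, scale: str | dict[str, float] = "eisenberg"
) -> float:
    """Arithmetic mean of the per-residue hydrophobicity index."""
    sequence = _as_str(seq)
    table = _scales.HYDROPHOBICITY_SCALES[scale] if isinstance(scale, str) else scale
    return sum(table[r] for r in sequence) / len(sequence)


def hydrophobic_moment(
    seq: PeptideSeq | str,
    scale: str | dict[str, float] = "eisenberg",
    angle_deg: float = 100.0,
) -> float:
    """Helical hydrophobic moment muH = |sum_k h_k (cos k*delta, sin k*delta)| / N.

    The default 100 degree turn angle corresponds to an ideal alpha-helix; an
    amphipathic sequence (hydrophobic residues clustered on one helix face)
    scores higher than a uniform one with the same mean.  muH is linear in the
    scale values (homogeneous of degree 1), not shift-invariant.
    """
    sequence = _as_str(seq)
    table = _scales.HYDROPHOBICITY_SCALES[scale] if isinstance(scale, str) else scale
    delta = math.radians(angle_deg)
    h = np.array([table[r] for r in sequence])
    k = np.arange(len(sequence))
    x = float(np.sum(h * np.cos(k * delta)))
    y = float(np.sum(h * np.sin(k * delta)))
    return math.hypot(x, y) / len(sequence)


@dataclass(frozen=True)
class FeatureVector:
    """AAC (20 fractions) and DPC (400 fractions) composition features.

    For single-residue sequences the DPC block is all-zero and
    ``dpc_defined`` is False.
    """

    aac: np.ndarray
    dpc: np.ndarray
    dpc_defined: bool

    def concat(self) -> np.ndarray:
        return np.concatenate([self.aac, self.dpc])


def composition_features(seq: PeptideSeq | str) -> FeatureVector:
    """Amino-acid and overlapping-dipeptide composition fractions.

    AAC = residue counts / N; DPC = dipeptide counts / (N - 1).
    """
    sequence = _as_str(seq)
    n = len(sequence)
    aac_index = {r: i for i, r in enumerate(AAC_ORDER)}
    aac = np.zeros(20)
    for r in sequence:
        aac[aac_index[r]] += 1.0
    aac /= n

    dpc = np.zeros(400)
    if n >= 2:
        dpc_index = {d: i for i, d in enumerate(DPC_ORDER)}
        for i in range(n - 1):
            dpc[dpc_index[sequence[i : i + 2]]] += 1.0
        dpc /= n - 1
        return FeatureVector(aac=aac, dpc=dpc, dpc_defined=True)
    return FeatureVector(aac=aac, dpc=dpc, dpc_defined=False)
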