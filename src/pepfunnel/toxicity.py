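"""SVM toxicity scorer over AAC/DPC composition features.

The classifier follows the ToxinPred recipe: peptides are embedded as amino
acid composition (AAC, 20 fractions), dipeptide composition (DPC, 400
fractions) or their concatenation, and a support vector machine separates
toxins from non-toxins.  The signed decision value is the "SVM score": values
above 0 are labelled Toxin, below 0 Non-Toxin, and larger values mean higher
confidence in toxicity.  Screening keeps peptides whose score falls in a
configurable band (default: score > -0.30 and label Non-Toxin).

The published training corpus is not shipped; models are trained on labelled
sets from :mod:`pepfunnel.synth` (planted compositional rule) or any
user-provided corpus.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .descriptors import composition_features
from .library import PeptideSeq, validate_sequence

__all__ = [
    "TOXIN",
    "NON_TOXIN",
    "ToxModel",
    "ToxScore",
    "featurize",
    "train_tox_model",
    "toxicity_score",
    "tox_band_filter",
]

TOXIN = "Toxin"
NON_TOXIN = "Non-Toxin"

_FEATURE_SPECS = ("aac", "dpc", "aac+dpc")


def featurize(sequences: list[str], feature_spec: str = "aac+dpc") -> np.ndarray:
    """Embed sequences as AAC, DPC or concatenated AAC+DPC fractions.

    Shares the exact code path with :func:`pepfunnel.descriptors.composition_features`.
    """
    if feature_spec not in _FEATURE_SPECS:
        raise ValueError(f"feature_spec must be one of {_FEATURE_SPECS}")
    rows = []
    for seq in sequences:
        fv = composition_features(seq)
        if feature_spec == "aac":
            rows.append(fv.aac)
        elif feature_spec == "dpc":
            rows.append(fv.dpc)
        else:
            rows.append(fv.concat())
    return np.asarray(rows)


@dataclass(frozen=True)
class ToxScore:
    """Signed SVM decision value plus its Toxin/Non-Toxin label."""

    value: float
    label: str

    @classmethod
    def from_value(cls, value: float, threshold: float = 0.0) -> "ToxScore":
        return cls(value=float(value), label=TOXIN if value > threshold else NON_TOXIN)


@dataclass
class ToxModel:
    """A trained toxicity SVM with its feature specification and metadata."""

    svc: SVC
    feature_spec: str
    kernel: str
    n_pos: int
    n_neg: int
    seed: int

    def decision_values(self, sequences: list[str]) -> np.ndarray:
        """Signed decision values; positive means Toxin."""
        x = featurize(sequences, self.feature_spec)
        return self.svc.decision_function(x)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ToxModel":
        model = joblib.load(path)
        if not isinstance(model, ToxModel):
            raise TypeError(f"{path} does not contain a ToxModel")
        return model


def train_tox_model(
    sequences: list[str],
    labels: list[str],
    feature_spec: str = "aac+dpc",
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
) -> ToxModel:
    """Fit the toxicity SVM on labelled peptides.

    ``labels`` are ``"Toxin"`` / ``"Non-Toxin"`` strings; at least two
    examples of each class are required.  Training is deterministic for a
    given seed (and, with the default linear kernel, independent of it).
    """
    sequences = [validate_sequence(s) for s in sequences]
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if set(classes) != {TOXIN, NON_TOXIN}:
        raise ValueError(
            f"labels must contain both {TOXIN!r} and {NON_TOXIN!r}; got {set(classes)}"
        )
    if counts.min() < 2:
        raise ValueError("need at least 2 examples per class")
    x = featurize(sequences, feature_spec)
    # y encoded 0/1 so that decision_function > 0 <=> Toxin
    y_bin = (y == TOXIN).astype(int)
    svc = SVC(kernel=kernel, C=C, random_state=seed)
    svc.fit(x, y_bin)
    n_pos = int((y_bin == 1).sum())
    return ToxModel(
        svc=svc,
        feature_spec=feature_spec,
        kernel=kernel,
        n_pos=n_pos,
        n_neg=len(y_bin) - n_pos,
        seed=seed,
    )


def toxicity_score(
    model: ToxModel, seq: PeptideSeq | str, threshold: float = 0.0
) -> ToxScore:
    """Score one peptide: signed decision value plus label at ``threshold``."""
    sequence = seq.sequence if isinstance(seq, PeptideSeq) else validate_sequence(seq)
    value = float(model.decision_values([sequence])[0])
    return ToxScore.from_value(value, threshold)


def tox_band_filter(
    scores: dict[str, ToxScore],
    lower: float = -0.30,
    upper: float = float("inf"),
    require_label: str | None = NON_TOXIN,
) -> list[str]:
    """Ids whose score lies strictly above ``lower``, at or below ``upper``,
    and (by default) whose label is Non-Toxin.

    This is the screening band of the funnel: scores in (-0.30, 0] survive,
    scores at or below -0.30 and Toxin-labelled peptides do not.
    """
    if lower > upper:
        raise ValueError("lower bound exceeds upper bound")
    retained = []
    for pid, score in scores.items():
        if score.value <= lower or score.value > upper:
            continue
        if require_label is not None and score.label != require_label:
            continue
        retained.append(pid)
    return retained
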