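"""Synthetic data generators for every statistical structure the pipeline
assumes.

All generators are pure functions of their parameters and a seed: labelled
toxin/non-toxin peptide sets with a planted compositional signal (cysteine /
lysine / arginine enrichment in the positive class — a documented synthetic
rule, not a biological truth), coordinate ensembles with known per-atom
fluctuation and block-correlation structure, and MM/GBSA component tables
with consistent (or deliberately corrupted) sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._scales import STANDARD_RESIDUES
from .energetics import EnergyRecord, assemble_energy_record
from .toxicity import NON_TOXIN, TOXIN
from .traj import TrajectoryEnsemble

__all__ = [
    "gen_peptide_set",
    "gen_toxicity_training",
    "CorrelatedBlock",
    "gen_trajectory",
    "gen_energy_table",
]

_ALPHABET = np.array(list(STANDARD_RESIDUES))


def _residue_weights(bias: dict[str, float] | None) -> np.ndarray:
    weights = np.ones(20)
    if bias:
        index = {r: i for i, r in enumerate(STANDARD_RESIDUES)}
        for res, w in bias.items():
            if w < 0:
                raise ValueError(f"negative weight for residue {res!r}")
            weights[index[res.upper()]] = w
    if weights.sum() <= 0:
        raise ValueError("all residue weights are zero")
    return weights / weights.sum()


def gen_peptide_set(
    n: int,
    length: int = 8,
    bias: dict[str, float] | None = None,
    seed: int = 0,
    id_prefix: str = "syn",
) -> list[tuple[str, str]]:
    """Random peptides drawn residue-wise from a (possibly biased) composition.

    ``bias`` maps residues to multiplicative weights relative to uniform.
    Returns ``(id, sequence)`` pairs, reproducible by seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = _residue_weights(bias)
    out = []
    for i in range(n):
        seq = "".join(rng.choice(_ALPHABET, size=length, p=p))
        out.append((f"{id_prefix}{i + 1}", seq))
    return out


def gen_toxicity_training(
    n_pos: int = 500,
    n_neg: int = 500,
    length: int = 15,
    enrichment: float = 5.0,
    cluster: bool = True,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Labelled training set with a planted toxicity rule.

    The Toxin class over-samples C, K and R by ``enrichment``-fold relative
    to uniform and, with ``cluster`` (default), arranges those residues as
    one contiguous run at a random offset — a synthetic caricature of the
    clustered cysteine/cationic motifs of real peptide toxins.  Clustering
    permutes residues only, so it is invisible to amino-acid composition but
    carries dipeptide-composition signal; composition-only and AAC+DPC
    models therefore have genuinely different ceilings on this benchmark.
    The Non-Toxin class is uniform.  ``enrichment=1`` with ``cluster=False``
    gives the null (indistinguishable classes).  Returns
    ``(sequences, labels)`` with exactly ``n_pos`` Toxin then ``n_neg``
    Non-Toxin entries.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both class sizes must be >= 1")
    if enrichment <= 1.0 and not cluster:
        import warnings

        warnings.warn(
            "enrichment <= 1 without clustering: classes are not separable "
            "by construction",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    p_pos = _residue_weights({"C": enrichment, "K": enrichment, "R": enrichment})
    sequences = []
    for _ in range(n_pos):
        residues = list(rng.choice(_ALPHABET, size=length, p=p_pos))
        if cluster:
            marked = [r for r in residues if r in "CKR"]
            rest = [r for r in residues if r not in "CKR"]
            if marked:
                offset = int(rng.integers(0, len(rest) + 1))
                residues = rest[:offset] + marked + rest[offset:]
        sequences.append("".join(residues))
    p_neg = _residue_weights(None)
    for _ in range(n_neg):
        sequences.append("".join(rng.choice(_ALPHABET, size=length, p=p_neg)))
    labels = [TOXIN] * n_pos + [NON_TOXIN] * n_neg
    return sequences, labels


@dataclass(frozen=True)
class CorrelatedBlock:
    """A group of atoms driven by one shared scalar mode.

    Every atom in the block moves along the same (randomly drawn) unit
    vector with per-frame amplitude ``amplitude * s_t``, ``s_t ~ N(0,1)``;
    per-atom ``signs`` of -1 yield anti-correlated motion within the block.
    """

    atoms: tuple[int, ...]
    amplitude: float = 1.0
    signs: tuple[int, ...] | None = None


def _helix_backbone(n_atoms: int) -> np.ndarray:
    """An idealised C-alpha helix as reference geometry (2.3 A radius,
    100 degree turn, 1.5 A rise)."""
    i = np.arange(n_atoms)
    theta = np.deg2rad(100.0) * i
    return np.column_stack(
        [2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i]
    )


def gen_trajectory(
    n_frames: int,
    n_atoms: int,
    sigma: float | np.ndarray = 0.5,
    blocks: list[CorrelatedBlock] = (),
    seed: int = 0,
) -> tuple[TrajectoryEnsemble, dict]:
    """Coordinate ensemble with known fluctuation and correlation structure.

    Per-atom displacements are isotropic Gaussians with per-axis standard
    deviation ``sigma`` plus the shared modes of ``blocks``.  Returns the
    ensemble and a ground-truth dict with the exact per-atom RMSF
    ``sqrt(3 sigma^2 + sum_b amplitude_b^2)`` and the block definitions, so
    estimators can be validated by parameter recovery.
    """
    if n_frames < 2 or n_atoms < 3:
        raise ValueError("need n_frames >= 2 and n_atoms >= 3")
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), (n_atoms,)).copy()
    if (sigma < 0).any():
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    base = _helix_backbone(n_atoms)
    coords = base[None, :, :] + rng.normal(
        scale=sigma[None, :, None], size=(n_frames, n_atoms, 3)
    )
    mode_var = np.zeros(n_atoms)
    block_info = []
    for block in blocks:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        signs = (
            np.ones(len(block.atoms))
            if block.signs is None
            else np.asarray(block.signs, dtype=float)
        )
        driver = rng.normal(size=n_frames)
        for atom, sgn in zip(block.atoms, signs):
            coords[:, atom, :] += (
                block.amplitude * sgn * driver[:, None] * direction[None, :]
            )
            mode_var[atom] += block.amplitude**2
        block_info.append(
            {"atoms": list(block.atoms), "amplitude": block.amplitude,
             "direction": direction, "signs": signs.tolist()}
        )
    truth = {
        "sigma": sigma,
        "rmsf": np.sqrt(3.0 * sigma**2 + mode_var),
        "blocks": block_info,
    }
    traj = TrajectoryEnsemble(
        coords=coords,
        residue_ids=np.arange(1, n_atoms + 1),
        residue_names=np.full(n_atoms, "ALA"),
        atom_names=np.full(n_atoms, "CA"),
        chain_ids=np.full(n_atoms, "A"),
        elements=np.full(n_atoms, "C"),
    )
    return traj, truth


def gen_energy_table(
    n: int,
    seed: int = 0,
    inject: dict | None = None,
) -> list[EnergyRecord]:
    """MM/GBSA records with components drawn in realistic ranges and all
    derived sums computed consistently.

    ``inject={"row": i, "field": name, "delta": x}`` adds ``x`` to one stored
    derived value after assembly, creating a bookkeeping inconsistency of
    known magnitude for audit tests.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        rec = assemble_energy_record(
            complex_id=f"synth{i + 1}",
            e_int=float(rng.uniform(-5, 5)),
            e_vdw=float(rng.uniform(-80, -20)),
            e_ele=float(rng.uniform(-300, 300)),
            g_gb=float(rng.uniform(-300, 300)),
            g_sa=float(rng.uniform(-10, -1)),
        )
        records.append(rec)
    if inject is not None:
        from dataclasses import replace

        i = inject["row"]
        field_name = inject["field"]
        rec = records[i]
        records[i] = replace(
            rec, **{field_name: getattr(rec, field_name) + inject["delta"]}
        )
    return records
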