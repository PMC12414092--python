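"""FASTA and table I/O plus packaged reference fixtures."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import descriptors
from .library import PeptideSeq

__all__ = [
    "read_fasta",
    "write_fasta",
    "descriptor_table",
    "load_table1_hits",
    "load_table4_energies",
    "load_pred_contributions",
]


def read_fasta(path: str | Path) -> list[PeptideSeq]:
    return [
        PeptideSeq(str(rec.seq), id=rec.id) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(peptides: list[PeptideSeq], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id or f"seq{i + 1}", description="")
        for i, p in enumerate(peptides)
    ]
    SeqIO.write(records, str(path), "fasta")


def descriptor_table(
    peptides: list[PeptideSeq],
    scale: str = "eisenberg",
    pka_set: str = "emboss",
) -> pd.DataFrame:
    """One row per peptide: id, sequence, masses, charge, pI, hydrophobicity
    and helical hydrophobic moment (amphipathicity)."""
    rows = []
    for p in peptides:
        rows.append(
            {
                "id": p.id,
                "sequence": p.sequence,
                "mw_avg": descriptors.molecular_weight(p, "average"),
                "mw_mono": descriptors.molecular_weight(p, "monoisotopic"),
                "net_charge": descriptors.net_charge(p),
                "pI": descriptors.isoelectric_point(p, pka_set),
                "hydrophobicity": descriptors.hydrophobicity_mean(p, scale),
                "amphipathicity": descriptors.hydrophobic_moment(p, scale),
            }
        )
    return pd.DataFrame(rows)


def _data_path(name: str):
    return resources.files("pepfunnel") / "data" / name


def load_table1_hits() -> pd.DataFrame:
    """The 16 screened hit peptides with their published descriptor columns
    (SVM score, prediction, hydrophobicity, amphipathicity, molecular weight,
    Na4vSS, folding energy).  Score columns come from external web servers
    whose scales are unpublished; they are inputs, not recomputed values."""
    with resources.as_file(_data_path("table1_hits.csv")) as p:
        return pd.read_csv(p)


def load_table4_energies() -> pd.DataFrame:
    """Published MM/GBSA component table for the peptide and reference
    inhibitor complexes (kcal/mol; sem_* columns are standard errors kept
    verbatim, including one typeset anomaly noted in the file header)."""
    with resources.as_file(_data_path("table4_mmgbsa.csv")) as p:
        return pd.read_csv(p, comment="#")


def load_pred_contributions() -> pd.DataFrame:
    """Published per-residue electrostatic contributions to binding
    (kcal/mol).  The source sentence lists four residue names against three
    leading values; the three values are stored against the first three
    names and the ambiguity is noted in the file header."""
    with resources.as_file(_data_path("pred_contributions.csv")) as p:
        return pd.read_csv(p, comment="#")
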