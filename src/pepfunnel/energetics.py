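"""MM/GBSA energy bookkeeping and per-residue contribution ranking.

The molecular-mechanics / generalised-Born surface-area decomposition splits
a binding free energy into a gas-phase term and a solvation term::

    E_gas  = E_int + E_vdw + E_ele
    G_sol  = G_GB + G_SA          with  G_SA = gamma * SASA
    dG_bind = E_gas + G_sol - T*dS

where gamma is the surface-tension coefficient (default 0.0072 kcal/mol/A^2,
paired with a 1.4 A water probe) and the entropy term T*dS is optional
(treated as 0 when absent, as is common when normal-mode analysis is
skipped).  This module does not compute the terms from trajectories; it
assembles, audits and ranks published or computed component tables —
e.g. verifying that a table's printed sums actually add up.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "GAMMA_DEFAULT",
    "EnergyRecord",
    "AuditFlag",
    "ResidueContribution",
    "assemble_energy_record",
    "binding_from_states",
    "audit_energy_record",
    "rank_residue_contributions",
    "read_energy_csv",
    "write_energy_csv",
]

GAMMA_DEFAULT = 0.0072  # kcal/mol/A^2, with a 1.4 A water probe

_CSV_COLUMNS = [
    "complex_id", "e_int", "e_vdw", "e_ele", "g_gb", "g_sa",
    "sasa", "gamma", "tds", "e_gas", "g_sol", "dg_bind",
]


@dataclass(frozen=True)
class EnergyRecord:
    """MM/GBSA component terms and derived sums for one complex.

    All energies in kcal/mol, SASA in A^2.  ``e_gas``, ``g_sol`` and
    ``dg_bind`` hold the *stored* (e.g. printed) values; the ``derived_*``
    methods recompute them from components so the audit can compare the two.
    """

    complex_id: str
    e_int: float | None = None
    e_vdw: float | None = None
    e_ele: float | None = None
    g_gb: float | None = None
    g_sa: float | None = None
    sasa: float | None = None
    gamma: float = GAMMA_DEFAULT
    tds: float | None = None
    e_gas: float | None = None
    g_sol: float | None = None
    dg_bind: float | None = None

    def has_gas_components(self) -> bool:
        return self.e_vdw is not None and self.e_ele is not None

    def derived_e_gas(self) -> float | None:
        """E_int + E_vdw + E_ele (E_int taken as 0 when absent)."""
        if not self.has_gas_components():
            return None
        return (self.e_int or 0.0) + self.e_vdw + self.e_ele

    def derived_g_sol(self) -> float | None:
        if self.g_gb is None or self.g_sa is None:
            return None
        return self.g_gb + self.g_sa

    def derived_g_sa(self) -> float | None:
        """gamma * SASA when a surface area is recorded."""
        if self.sasa is None:
            return None
        return self.gamma * self.sasa

    def derived_dg_bind(self) -> float | None:
        e_gas = self.e_gas if self.e_gas is not None else self.derived_e_gas()
        g_sol = self.g_sol if self.g_sol is not None else self.derived_g_sol()
        if e_gas is None or g_sol is None:
            return None
        return e_gas + g_sol - (self.tds or 0.0)


def assemble_energy_record(
    complex_id: str,
    e_int: float | None = None,
    e_vdw: float | None = None,
    e_ele: float | None = None,
    g_gb: float | None = None,
    g_sa: float | None = None,
    sasa: float | None = None,
    gamma: float = GAMMA_DEFAULT,
    tds: float | None = None,
    e_gas: float | None = None,
    g_sol: float | None = None,
    dg_bind: float | None = None,
) -> EnergyRecord:
    """Build a record and fill the derived sums that were not supplied.

    Requires G_GB and G_SA (or a SASA to derive G_SA from), plus either
    E_gas or its components.
    """
    if g_sa is None and sasa is not None:
        g_sa = gamma * sasa
    rec = EnergyRecord(
        complex_id=complex_id, e_int=e_int, e_vdw=e_vdw, e_ele=e_ele,
        g_gb=g_gb, g_sa=g_sa, sasa=sasa, gamma=gamma, tds=tds,
        e_gas=e_gas, g_sol=g_sol, dg_bind=dg_bind,
    )
    if rec.e_gas is None and not rec.has_gas_components():
        raise ValueError(
            f"{complex_id}: need E_gas or its components (E_vdw and E_ele)"
        )
    if rec.g_gb is None or rec.g_sa is None:
        raise ValueError(f"{complex_id}: need G_GB and G_SA (or SASA)")
    updates = {}
    if rec.e_gas is None:
        updates["e_gas"] = rec.derived_e_gas()
    if rec.g_sol is None:
        updates["g_sol"] = rec.derived_g_sol()
    rec = replace(rec, **updates)
    if rec.dg_bind is None:
        rec = replace(rec, dg_bind=rec.derived_dg_bind())
    return rec


def binding_from_states(
    complex_id: str,
    complex_terms: dict[str, float],
    receptor_terms: dict[str, float],
    ligand_terms: dict[str, float],
    gamma: float = GAMMA_DEFAULT,
    tds: float | None = None,
) -> EnergyRecord:
    """Endpoint form dG_bind = G_complex - G_receptor - G_ligand.

    Each state dict supplies per-term absolute energies (keys among
    ``e_int, e_vdw, e_ele, g_gb, g_sa``); the per-term differences are
    assembled exactly like the component form, so the two constructions
    agree on consistent inputs.
    """
    keys = ("e_int", "e_vdw", "e_ele", "g_gb", "g_sa")
    deltas = {}
    for key in keys:
        if key in complex_terms and key in receptor_terms and key in ligand_terms:
            deltas[key] = complex_terms[key] - receptor_terms[key] - ligand_terms[key]
    return assemble_energy_record(complex_id, gamma=gamma, tds=tds, **deltas)


@dataclass(frozen=True)
class AuditFlag:
    """One failed bookkeeping identity: the stored vs recomputed value."""

    complex_id: str
    identity: str
    stored: float
    computed: float

    @property
    def discrepancy(self) -> float:
        return abs(self.stored - self.computed)


def audit_energy_record(rec: EnergyRecord, tolerance: float = 0.05) -> list[AuditFlag]:
    """Re-evaluate every derivable identity; flag mismatches beyond tolerance.

    The default tolerance of 0.05 kcal/mol absorbs two-decimal rounding of
    each operand.  Identities checked when both sides are available:
    gas sum, solvation sum, gamma*SASA, and the total binding energy.
    """
    flags = []
    checks = [
        ("e_gas = e_int + e_vdw + e_ele", rec.e_gas, rec.derived_e_gas()),
        ("g_sol = g_gb + g_sa", rec.g_sol, rec.derived_g_sol()),
        ("g_sa = gamma * sasa", rec.g_sa, rec.derived_g_sa()),
        ("dg_bind = e_gas + g_sol - tds", rec.dg_bind, rec.derived_dg_bind()),
    ]
    for name, stored, computed in checks:
        if stored is None or computed is None:
            continue
        if abs(stored - computed) > tolerance:
            flags.append(
                AuditFlag(
                    complex_id=rec.complex_id,
                    identity=name,
                    stored=float(stored),
                    computed=float(computed),
                )
            )
    return flags


@dataclass(frozen=True)
class ResidueContribution:
    """Per-residue energy decomposition entry (e.g. 'ARG 628')."""

    residue: str
    e_ele: float | None = None
    e_vdw: float | None = None
    total: float | None = None


def rank_residue_contributions(
    contribs: list[ResidueContribution], by: str = "e_ele"
) -> list[ResidueContribution]:
    """Ascending by the chosen term (most favourable, i.e. most negative,
    first); stable on ties."""
    if not contribs:
        raise ValueError("no residue contributions to rank")
    if any(getattr(c, by, None) is None for c in contribs):
        raise ValueError(f"field {by!r} missing on some contributions")
    return sorted(contribs, key=lambda c: getattr(c, by))


def read_energy_csv(path: str | Path) -> list[EnergyRecord]:
    """Read records from CSV (canonical column names; extra columns ignored)."""
    df = pd.read_csv(path, comment="#")
    records = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _CSV_COLUMNS:
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = row[col]
        kwargs["complex_id"] = str(kwargs["complex_id"])
        kwargs.setdefault("gamma", GAMMA_DEFAULT)
        records.append(EnergyRecord(**kwargs))
    return records


def write_energy_csv(records: list[EnergyRecord], path: str | Path) -> None:
    rows = [{col: getattr(r, col) for col in _CSV_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
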