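"""Free-energy threshold classification of mutation effects and
residue-to-interface distance annotation.

Mutations carry predicted changes in binding free energy (ddG_bind, toward
the partner GTPase) and in folding stability (ddG_stability), both in
kcal/mol with positive values destabilizing.  A mutation is called
*disruptive* when either value strictly exceeds the threshold (default
2 kcal/mol).  Truncations and deletions that remove the binding interface
outright carry no ddG values and are classified *interface_eliminated*.

Interface proximity is the minimum heavy-atom distance from a residue to any
atom of the partner chain, flagged at a 6 A cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import pandas as pd

__all__ = [
    "DdgRecord",
    "InterfaceAnnotation",
    "DISRUPTIVE",
    "NON_DISRUPTIVE",
    "INTERFACE_ELIMINATED",
    "classify_ddg",
    "count_disruptive",
    "star_mismatches",
    "interface_distance",
    "read_ddg_table",
]

DISRUPTIVE = "disruptive"
NON_DISRUPTIVE = "non_disruptive"
INTERFACE_ELIMINATED = "interface_eliminated"

DEFAULT_DDG_THRESHOLD = 2.0  # kcal/mol
DEFAULT_INTERFACE_CUTOFF = 6.0  # Angstrom


@dataclass(frozen=True)
class DdgRecord:
    """One mutation's predicted free-energy changes.

    ``ddg_bind`` and ``ddg_stability`` are either both present (point
    mutations) or both absent (interface-eliminating truncations/deletions).
    ``starred`` optionally carries an upstream prediction flag against which
    the threshold rule can be audited.
    """

    mutation_id: str
    ddg_bind: float | None = None
    ddg_stability: float | None = None
    dna_change: str = ""
    structural_note: str = ""
    starred: bool | None = None
    mclass: str = "missense"

    def __post_init__(self):
        if (self.ddg_bind is None) != (self.ddg_stability is None):
            raise ValueError(
                f"{self.mutation_id}: ddg_bind and ddg_stability must be "
                "both present or both absent"
            )


@dataclass(frozen=True)
class InterfaceAnnotation:
    residue_id: str
    min_distance: float
    within_cutoff: bool
    cutoff: float = DEFAULT_INTERFACE_CUTOFF


def classify_ddg(record: DdgRecord, threshold: float = DEFAULT_DDG_THRESHOLD) -> str:
    """Verdict for one record: strict ``> threshold`` on either ddG."""
    if record.ddg_bind is None:
        return INTERFACE_ELIMINATED
    if record.ddg_bind > threshold or record.ddg_stability > threshold:
        return DISRUPTIVE
    return NON_DISRUPTIVE


def count_disruptive(
    records: list[DdgRecord],
    threshold: float = DEFAULT_DDG_THRESHOLD,
    restrict_to: str | None = None,
) -> int:
    """Number of disruptive verdicts, optionally over one mutation class."""
    total = 0
    for rec in records:
        if restrict_to is not None and rec.mclass != restrict_to:
            continue
        total += classify_ddg(rec, threshold) == DISRUPTIVE
    return total


def star_mismatches(
    records: list[DdgRecord], threshold: float = DEFAULT_DDG_THRESHOLD
) -> list[str]:
    """Mutations whose threshold verdict disagrees with the upstream
    prediction flag; surfaced rather than silently reconciled."""
    bad = []
    for rec in records:
        if rec.starred is None or rec.ddg_bind is None:
            continue
        if (classify_ddg(rec, threshold) == DISRUPTIVE) != rec.starred:
            bad.append(rec.mutation_id)
    return bad


def _load_structure(structure: str | Path | gemmi.Structure) -> gemmi.Structure:
    if isinstance(structure, gemmi.Structure):
        return structure
    st = gemmi.read_structure(str(structure))
    if len(st) == 0 or all(len(chain) == 0 for chain in st[0]):
        raise ValueError(f"structure {structure} has no coordinates")
    return st


def interface_distance(
    structure: str | Path | gemmi.Structure,
    residue: tuple[str, int],
    partner_chain: str,
    cutoff: float = DEFAULT_INTERFACE_CUTOFF,
    include_hydrogens: bool = False,
) -> InterfaceAnnotation:
    """Minimum distance (A) from a residue's atoms to any partner-chain atom.

    Hydrogens are excluded by default: crystal structures typically lack
    them and interface statements at this resolution refer to heavy atoms.
    """
    st = _load_structure(structure)
    model = st[0]
    chain_id, seq_num = residue

    def atoms_of(chain: gemmi.Chain, seqid: int | None):
        for res in chain:
            if seqid is not None and res.seqid.num != seqid:
                continue
            for atom in res:
                if not include_hydrogens and atom.is_hydrogen():
                    continue
                yield atom.pos

    chain = model.find_chain(chain_id)
    if chain is None:
        raise KeyError(f"chain {chain_id!r} not found")
    res_atoms = list(atoms_of(chain, seq_num))
    if not res_atoms:
        raise KeyError(f"residue {chain_id}/{seq_num} not found or has no heavy atoms")
    partner = model.find_chain(partner_chain)
    if partner is None:
        raise KeyError(f"partner chain {partner_chain!r} not found")
    partner_atoms = list(atoms_of(partner, None))
    if not partner_atoms:
        raise KeyError(f"partner chain {partner_chain!r} has no heavy atoms")
    dmin = min(a.dist(b) for a in res_atoms for b in partner_atoms)
    return InterfaceAnnotation(
        residue_id=f"{chain_id}/{seq_num}",
        min_distance=float(dmin),
        within_cutoff=dmin <= cutoff,
        cutoff=cutoff,
    )


def read_ddg_table(path: str | Path) -> list[DdgRecord]:
    """Read a ddG TSV (mutation_protein, mutation_dna, ddg_bind,
    ddg_stability, starred, mclass, note); '-' or blank marks absent ddG."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype=str)

    def num(value):
        if pd.isna(value) or str(value).strip() in ("", "-", "--"):
            return None
        return float(value)

    records = []
    for _, row in table.iterrows():
        starred = row.get("starred")
        records.append(
            DdgRecord(
                mutation_id=row["mutation_protein"],
                dna_change="" if pd.isna(row.get("mutation_dna")) else row["mutation_dna"],
                ddg_bind=num(row.get("ddg_bind")),
                ddg_stability=num(row.get("ddg_stability")),
                structural_note="" if pd.isna(row.get("note")) else row["note"],
                starred=None if pd.isna(starred) else bool(int(starred)),
                mclass=row.get("mclass", "missense") if not pd.isna(row.get("mclass")) else "missense",
            )
        )
    return records
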