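"""Parsing of peptide–HLA conformations into a neutral structure record.

A pHLA complex is represented as two ordered lists of residues — the peptide
and the HLA receptor chain — each residue carrying its heavy-atom (non-
hydrogen) coordinates in Ångström.  Everything downstream (featurization,
classification, interpretation) consumes only this record, so the source of
the coordinates (docking output, crystal structure, synthetic toy) is
irrelevant past this point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

logger = logging.getLogger(__name__)

#: Three-letter -> one-letter codes for the 20 standard amino acids.
THREE_TO_ONE: Mapping[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ONE_TO_THREE: Mapping[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"


class StructureError(ValueError):
    """Raised when a file cannot be interpreted as a pHLA complex."""


@dataclass(frozen=True)
class Residue:
    """One amino-acid residue: 1-based position, one-letter code, heavy atoms.

    ``heavy_atoms`` is an (n_atoms, 3) float array of coordinates in Å.
    """

    position: int
    aa: str
    heavy_atoms: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.heavy_atoms, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 1:
            raise ValueError(
                f"residue {self.aa}{self.position}: heavy_atoms must be a "
                f"non-empty (n, 3) array, got shape {coords.shape}"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(
                f"residue {self.aa}{self.position}: non-finite coordinates"
            )
        if self.aa not in ONE_TO_THREE:
            raise ValueError(f"non-standard amino acid code {self.aa!r}")
        object.__setattr__(self, "heavy_atoms", coords)


@dataclass
class StructureRecord:
    """A single pHLA conformation: peptide residues + HLA receptor residues."""

    phla_id: str
    conformation_id: str
    peptide_residues: list[Residue]
    hla_residues: list[Residue]

    def __post_init__(self) -> None:
        if len(self.peptide_residues) < 1:
            raise ValueError("peptide chain has zero standard residues")
        if len(self.hla_residues) < 1:
            raise ValueError("HLA chain has zero standard residues")
        positions = [r.position for r in self.peptide_residues]
        if positions != list(range(1, len(positions) + 1)):
            raise ValueError(
                f"peptide positions must be contiguous from 1, got {positions}"
            )

    @property
    def peptide_sequence(self) -> str:
        return "".join(r.aa for r in self.peptide_residues)

    @property
    def hla_sequence(self) -> str:
        return "".join(r.aa for r in self.hla_residues)


def _pick_altloc(atom):
    """Resolve a possibly disordered atom to a single position.

    Highest occupancy wins; ties broken by altloc identifier order.
    """
    if not atom.is_disordered():
        return atom
    candidates = atom.disordered_get_list()
    return min(candidates, key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()))


def _is_hydrogen(atom) -> bool:
    element = (atom.element or "").strip().upper()
    if element:
        return element in ("H", "D")
    # Fallback heuristic on the atom name: strip leading digits (e.g. 1HB).
    name = atom.get_name().strip().lstrip("0123456789")
    return name.startswith(("H", "D"))


def _chain_to_residues(chain, renumber_from_one: bool) -> list[Residue]:
    residues: list[Residue] = []
    next_pos = 1
    for res in chain:
        resname = res.get_resname().strip().upper()
        if resname not in THREE_TO_ONE:
            if res.id[0].strip():  # HETATM (water, ligands, modified residues)
                logger.warning(
                    "skipping non-standard residue %s %s in chain %s",
                    resname, res.id, chain.id,
                )
            else:
                logger.warning(
                    "skipping unrecognized ATOM residue %s %s in chain %s",
                    resname, res.id, chain.id,
                )
            continue
        coords = []
        for atom in res:
            picked = _pick_altloc(atom)
            if _is_hydrogen(picked):
                continue
            coords.append(np.asarray(picked.get_coord(), dtype=float))
        if not coords:
            logger.warning(
                "residue %s %s in chain %s has no heavy atoms; skipped",
                resname, res.id, chain.id,
            )
            continue
        pos = next_pos if renumber_from_one else int(res.id[1])
        residues.append(Residue(pos, THREE_TO_ONE[resname], np.asarray(coords)))
        next_pos += 1
    return residues


def parse_structure(
    pdb_path: str | Path,
    chain_map: Mapping[str, str] | None = None,
    phla_id: str | None = None,
    conformation_id: str | None = None,
) -> StructureRecord:
    """Parse a PDB file into a :class:`StructureRecord`.

    Parameters
    ----------
    pdb_path
        Path to a PDB file with at least two protein chains.
    chain_map
        Optional explicit assignment mapping chain identifiers to the roles
        ``"peptide"`` or ``"hla"`` (e.g. ``{"C": "peptide", "A": "hla"}``).
        Chains not listed are excluded.  When absent, the shortest protein
        chain is taken as the peptide; with exactly two protein chains the
        other is the HLA, otherwise the longest remaining chain is kept as
        the HLA heavy chain and additional chains (such as
        β2-microglobulin) are excluded with a log message.
    phla_id, conformation_id
        Identifiers stored on the record; default to the file stem.

    Notes
    -----
    Hydrogens are excluded.  Non-standard residues (HETATM ligands, waters,
    modified amino acids) are skipped with a logged warning.  For disordered
    atoms the highest-occupancy alternate location is kept.
    """
    pdb_path = Path(pdb_path)
    if not pdb_path.exists():
        raise FileNotFoundError(str(pdb_path))

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        model = next(parser.get_structure(pdb_path.stem, str(pdb_path)).get_models())

    chains = {}
    for chain in model:
        residues = _chain_to_residues(chain, renumber_from_one=False)
        if residues:
            chains[chain.id] = residues
    if len(chains) < 2 and chain_map is None:
        raise StructureError(
            f"{pdb_path.name}: found {len(chains)} protein chain(s); "
            "a pHLA complex needs a peptide chain and an HLA chain"
        )

    if chain_map is not None:
        roles = {str(v).lower() for v in chain_map.values()}
        if not roles <= {"peptide", "hla"}:
            raise StructureError(f"chain_map roles must be peptide/hla, got {roles}")
        pep_ids = [c for c, r in chain_map.items() if str(r).lower() == "peptide"]
        hla_ids = [c for c, r in chain_map.items() if str(r).lower() == "hla"]
        if len(pep_ids) != 1 or not hla_ids:
            raise StructureError(
                "chain_map must assign exactly one peptide chain and >=1 HLA chain"
            )
        missing = [c for c in pep_ids + hla_ids if c not in chains]
        if missing:
            raise StructureError(
                f"{pdb_path.name}: chain(s) {missing} absent or without "
                "standard residues"
            )
        pep_id = pep_ids[0]
        hla_residues = [r for cid in hla_ids for r in chains[cid]]
    else:
        pep_id = min(chains, key=lambda c: (len(chains[c]), c))
        others = [c for c in chains if c != pep_id]
        if len(others) > 1:
            keep = max(others, key=lambda c: (len(chains[c]), c))
            dropped = sorted(set(others) - {keep})
            logger.info(
                "%s: multiple receptor chains; keeping longest chain %s as HLA, "
                "excluding %s (pass chain_map to override)",
                pdb_path.name, keep, dropped,
            )
            others = [keep]
        hla_residues = [r for cid in others for r in chains[cid]]

    peptide = [
        Residue(i + 1, r.aa, r.heavy_atoms)
        for i, r in enumerate(chains[pep_id])
    ]
    if not peptide:
        raise StructureError(f"{pdb_path.name}: peptide chain has no standard residues")

    return StructureRecord(
        phla_id=phla_id if phla_id is not None else pdb_path.stem,
        conformation_id=conformation_id if conformation_id is not None else pdb_path.stem,
        peptide_residues=peptide,
        hla_residues=hla_residues,
    )


def write_pdb(record: StructureRecord, path: str | Path) -> Path:
    """Write a :class:`StructureRecord` to a minimal PDB file.

    The peptide is emitted as chain ``C`` and the HLA as chain ``A``.  Atom
    identities beyond the element are not stored on the record, so atoms are
    written as generic carbons; residue types and coordinates round-trip.
    """
    path = Path(path)
    lines: list[str] = []
    serial = 1

    def emit(residues: Sequence[Residue], chain_id: str) -> None:
        nonlocal serial
        for res in residues:
            resname = ONE_TO_THREE[res.aa]
            for j, (x, y, z) in enumerate(res.heavy_atoms):
                name = f"C{j + 1}"
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {chain_id}"
                    f"{res.position:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {'C':>2s}"
                )
                serial += 1
        lines.append("TER")

    emit(record.hla_residues, "A")
    emit(record.peptide_residues, "C")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
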