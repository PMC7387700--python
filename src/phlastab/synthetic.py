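"""Synthetic pHLA geometries and planted-signal datasets.

Real pHLA conformations come from docking/modeling pipelines that are far
too expensive to run inside a test suite, so this module fabricates minimal
complexes whose *minimum heavy-atom distances* — the only structural
quantity featurization consumes — are controlled exactly.

Residues are rigid idealized templates (3–14 heavy atoms, matching the
heavy-atom count of each amino acid) with a designated contact atom; a
geometry rule prescribes the target minimum distance for chosen
(peptide position, HLA position) pairs and the builder realizes each target
to within 0.1 Å before optional coordinate jitter.

The planted-signal generator builds labeled datasets in which stable
examples carry designated amino-acid-pair contacts at a short "signal"
distance (default 3 Å) and unstable examples carry the same pair at a long
"background" distance (default 9 Å): the classes differ in geometry, not in
composition, so a classifier must read the structure.  Class balance,
conformation counts and the affinity annotations of negatives follow the
conditions of the real data: a 70:30 stable:unstable ratio, a median of
about 18 conformations per pHLA, and negative affinities above the
20,000 nM cutoff — plus a contaminating sub-threshold fraction so the label
filter is exercised non-trivially.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import MemoryStore, phla_id_of
from .featurize import pair_index
from .structure import STANDARD_AAS, Residue, StructureRecord, write_pdb

logger = logging.getLogger(__name__)

#: Heavy-atom counts of the 20 standard amino acids (backbone + side chain).
HEAVY_ATOM_COUNTS: Mapping[str, int] = {
    "G": 4, "A": 5, "S": 6, "C": 6, "T": 7, "V": 7, "P": 7, "D": 8,
    "N": 8, "I": 8, "L": 8, "M": 8, "E": 9, "Q": 9, "K": 9, "H": 10,
    "F": 11, "R": 11, "W": 14, "Y": 12,
}


class InfeasibleGeometryError(ValueError):
    """A geometry rule cannot be realized (conflicting distance targets)."""


@dataclass
class ToySpec:
    """Recipe for one synthetic pHLA complex.

    ``contacts`` maps (peptide position, HLA position), both 1-based, to a
    target minimum heavy-atom distance in Å.  Unlisted residue pairs sit at
    whatever distance the layout yields (far from the interface for
    untargeted HLA residues).  ``n_conformations`` jittered copies are
    produced, with isotropic Gaussian coordinate noise of ``noise_sd`` Å.
    """

    peptide: str
    hla: str
    contacts: Mapping[tuple[int, int], float] = field(default_factory=dict)
    n_conformations: int = 1
    noise_sd: float = 0.0
    seed: int = 0
    phla_id: str = ""
    allele: str = "HLA-A*01:01"

    def __post_init__(self) -> None:
        for seq, name in ((self.peptide, "peptide"), (self.hla, "hla")):
            if not seq or not set(seq) <= set(STANDARD_AAS):
                raise ValueError(f"{name} sequence must be non-empty over the 20-letter alphabet")
        for (p, h), d in self.contacts.items():
            if not (1 <= p <= len(self.peptide)) or not (1 <= h <= len(self.hla)):
                raise ValueError(f"contact ({p},{h}) outside sequence ranges")
            if d <= 0.5:
                raise ValueError(f"target distance for ({p},{h}) must exceed 0.5 Å")
        if not self.phla_id:
            self.phla_id = phla_id_of(self.peptide, self.allele)


_PEPTIDE_SPACING = 7.0   # Å between consecutive peptide residue contact atoms
_ATOM_STEP = 1.5         # Å between template atoms


def _template(aa: str, direction: np.ndarray) -> np.ndarray:
    """Heavy-atom template: contact atom at the origin, the rest trailing
    away along ``direction`` in a narrow zig-zag so the contact atom is
    always the nearest atom to anything approached head-on."""
    n = HEAVY_ATOM_COUNTS[aa]
    direction = direction / np.linalg.norm(direction)
    # two unit vectors orthogonal to direction
    helper = np.array([1.0, 0.0, 0.0])
    if abs(direction @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, helper)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    atoms = [np.zeros(3)]
    for k in range(1, n):
        lateral = 0.5 * ((-1) ** k) * u + 0.3 * ((-1) ** (k // 2)) * v
        atoms.append(k * _ATOM_STEP * direction + lateral)
    return np.asarray(atoms)


def build_toy_structure(spec: ToySpec) -> list[StructureRecord]:
    """Realize a :class:`ToySpec` as jittered conformations.

    The unjittered layout places peptide residues along the x axis with
    contact atoms facing +y, and each targeted HLA residue head-on at its
    target distance (direction fanned out per residue so neighbours do not
    interfere); untargeted HLA residues sit on a distant back plane.
    Realized minimum distances are checked against every target to 0.1 Å
    and an :class:`InfeasibleGeometryError` names conflicting pairs.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_pep, n_hla = len(spec.peptide), len(spec.hla)

    pep_centers = [np.array([i * _PEPTIDE_SPACING, 0.0, 0.0]) for i in range(n_pep)]
    pep_atoms = [
        pep_centers[i] + _template(spec.peptide[i], np.array([0.0, -1.0, 0.0]))
        for i in range(n_pep)
    ]

    targets_by_hla: dict[int, list[tuple[int, float]]] = {}
    for (p, h), d in spec.contacts.items():
        targets_by_hla.setdefault(h, []).append((p, d))

    hla_atoms: list[np.ndarray] = []
    fan_count = 0
    for j in range(1, n_hla + 1):
        aa = spec.hla[j - 1]
        if j in targets_by_hla:
            # anchor the residue on its first target, verify the rest below
            (p, d) = sorted(targets_by_hla[j])[0]
            angle = np.deg2rad(((fan_count * 47) % 120) - 60)
            fan_count += 1
            direction = np.array([0.0, np.cos(angle), np.sin(angle)])
            contact_point = pep_centers[p - 1] + d * direction
            atoms = contact_point + _template(aa, direction)
        else:
            row, col = divmod(j - 1, 8)
            base = np.array([col * 3.5 - 2.0, 14.0 + 4.0 * row, 6.0])
            atoms = base + _template(aa, np.array([0.0, 1.0, 0.0]))
        hla_atoms.append(atoms)

    # verify every target against the realized layout
    conflicts = []
    for (p, h), d in sorted(spec.contacts.items()):
        realized = float(
            np.min(
                np.linalg.norm(
                    pep_atoms[p - 1][:, None, :] - hla_atoms[h - 1][None, :, :],
                    axis=-1,
                )
            )
        )
        if abs(realized - d) > 0.1:
            conflicts.append(((p, h), d, realized))
    if conflicts:
        detail = "; ".join(
            f"pair (pep {p}, hla {h}): target {d:.2f} Å, realized {r:.2f} Å"
            for (p, h), d, r in conflicts
        )
        raise InfeasibleGeometryError(
            f"{spec.phla_id}: conflicting distance targets — {detail}"
        )

    records = []
    for c in range(spec.n_conformations):
        conf_id = f"conf{c:03d}"

        def jitter(atoms: np.ndarray) -> np.ndarray:
            if spec.noise_sd > 0:
                atoms = atoms + rng.normal(0.0, spec.noise_sd, atoms.shape)
            # quantize to PDB coordinate precision so written files are lossless
            return np.round(atoms, 3)

        records.append(
            StructureRecord(
                phla_id=spec.phla_id,
                conformation_id=conf_id,
                peptide_residues=[
                    Residue(i + 1, spec.peptide[i], jitter(pep_atoms[i]))
                    for i in range(n_pep)
                ],
                hla_residues=[
                    Residue(j + 1, spec.hla[j], jitter(hla_atoms[j]))
                    for j in range(n_hla)
                ],
            )
        )
    return records


@dataclass
class PlantedDatasetSpec:
    """Conditions for a planted-signal labeled dataset.

    Defaults follow the real-data conditions: a 70:30 stable:unstable ratio
    per allele, about 18 conformations per pHLA, and synthetic negative
    affinities log-uniform on (20,000, 50,000] nM, with a contaminating 10%
    of sub-threshold rows that the label filter must remove.
    """

    alleles: Sequence[str] = ("HLA-A*01:01", "HLA-A*02:01", "HLA-B*07:02")
    n_positives: int = 28
    n_negatives: int = 12
    signal_pairs: Sequence[tuple[str, str]] = (("R", "D"),)
    signal_distance: float = 3.0
    background_distance: float = 9.0
    label_noise: float = 0.0
    contamination: float = 0.1
    mean_conformations: int = 18
    noise_sd: float = 0.3
    peptide_length: int = 9
    hla_length: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positives + self.n_negatives == 0:
            raise ValueError("zero examples requested")
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label-noise rate must be in [0, 0.5)")
        for a, b in self.signal_pairs:
            pair_index(a, b)  # validates the codes

    @property
    def signal_feature_indices(self) -> list[int]:
        return sorted({pair_index(a, b) for a, b in self.signal_pairs})


@dataclass
class PlantedDataset:
    """A generated dataset: conformation store + label tables + ground truth."""

    store: MemoryStore
    positives: pd.DataFrame
    negatives: pd.DataFrame
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        """Materialize as the on-disk layout the real pipeline consumes."""
        out_dir = Path(out_dir)
        structures = out_dir / "structures"
        structures.mkdir(parents=True, exist_ok=True)
        for phla_id in self.store.phla_ids():
            d = structures / phla_id
            d.mkdir(exist_ok=True)
            for conf_id, rec in self.store.conformations(phla_id):
                write_pdb(rec, d / f"{conf_id}.pdb")
        self.positives.to_csv(out_dir / "positives.csv", index=False)
        self.negatives.to_csv(out_dir / "negatives.csv", index=False)
        (out_dir / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return out_dir


def _random_sequence(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def generate_planted_dataset(spec: PlantedDatasetSpec) -> PlantedDataset:
    """Generate structures and label tables with a planted geometric signal.

    Every example contains the signal amino-acid pairs at the interface;
    stable (true-label 1) examples place them at ``signal_distance``,
    unstable ones at ``background_distance``.  Anchor-like contacts at
    peptide positions 2 and the C-terminus (4 Å) are present in both
    classes.  Label noise flips the *recorded* label of a fraction of
    examples, leaving the geometry at its true class.  Contaminated
    negative rows (affinity below 20,000 nM) are appended beyond
    ``n_negatives``; they carry unstable geometry and are counted in the
    manifest so filter behavior can be checked against ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    signal_aas = {a for p in spec.signal_pairs for a in p}
    background_alphabet = "".join(a for a in STANDARD_AAS if a not in signal_aas)

    # designated positions: signal pair m sits at peptide pos 3+m (1-based)
    # and HLA pos 5+m; anchors (pep 2 and C-terminus) contact HLA pos 1, 2.
    sig_pep_pos = [3 + m for m in range(len(spec.signal_pairs))]
    sig_hla_pos = [5 + m for m in range(len(spec.signal_pairs))]
    if max(sig_pep_pos, default=0) > spec.peptide_length - 1:
        raise ValueError("too many signal pairs for the peptide length")
    if max(sig_hla_pos, default=0) > spec.hla_length:
        raise ValueError("too many signal pairs for the HLA length")

    hla_seqs: dict[str, str] = {}
    for allele in spec.alleles:
        seq = list(_random_sequence(rng, background_alphabet, spec.hla_length))
        for m, (_, hla_aa) in enumerate(spec.signal_pairs):
            seq[sig_hla_pos[m] - 1] = hla_aa
        hla_seqs[allele] = "".join(seq)

    records: dict[str, list[StructureRecord]] = {}
    pos_rows, neg_rows = [], []
    truth: dict[str, int] = {}
    n_flipped = 0
    n_contaminated = int(round(spec.contamination * spec.n_negatives * len(spec.alleles)))

    def make_example(allele: str, true_label: int, recorded_label: int,
                     affinity: float | None) -> None:
        nonlocal n_flipped
        while True:
            pep = list(_random_sequence(rng, background_alphabet, spec.peptide_length))
            for m, (pep_aa, _) in enumerate(spec.signal_pairs):
                pep[sig_pep_pos[m] - 1] = pep_aa
            peptide = "".join(pep)
            if phla_id_of(peptide, allele) not in records:
                break
        phla_id = phla_id_of(peptide, allele)
        contact_d = spec.signal_distance if true_label else spec.background_distance
        contacts = {
            (sig_pep_pos[m], sig_hla_pos[m]): contact_d
            for m in range(len(spec.signal_pairs))
        }
        contacts[(2, 1)] = 4.0
        contacts[(spec.peptide_length, 2)] = 4.0
        n_conf = max(1, int(rng.poisson(spec.mean_conformations)))
        toy = ToySpec(
            peptide=peptide,
            hla=hla_seqs[allele],
            contacts=contacts,
            n_conformations=n_conf,
            noise_sd=spec.noise_sd,
            seed=int(rng.integers(2**31 - 1)),
            allele=allele,
        )
        records[phla_id] = build_toy_structure(toy)
        truth[phla_id] = true_label
        if recorded_label != true_label:
            n_flipped += 1
        if recorded_label == 1:
            pos_rows.append({"peptide": peptide, "allele": allele})
        else:
            aff = affinity if affinity is not None else float(
                np.exp(rng.uniform(np.log(20_001.0), np.log(50_000.0)))
            )
            neg_rows.append({"peptide": peptide, "allele": allele, "affinity_nM": aff})

    for allele in spec.alleles:
        for _ in range(spec.n_positives):
            true = 1
            rec = 1 - true if rng.random() < spec.label_noise else true
            make_example(allele, true, rec, None)
        for _ in range(spec.n_negatives):
            true = 0
            rec = 1 - true if rng.random() < spec.label_noise else true
            make_example(allele, true, rec, None)

    # contaminated sub-threshold negatives, spread across alleles
    for i in range(n_contaminated):
        allele = spec.alleles[i % len(spec.alleles)]
        aff = float(np.exp(rng.uniform(np.log(100.0), np.log(20_000.0))))
        make_example(allele, 0, 0, aff)

    manifest = {
        "alleles": list(spec.alleles),
        "signal_pairs": [list(p) for p in spec.signal_pairs],
        "signal_feature_indices": spec.signal_feature_indices,
        "signal_distance": spec.signal_distance,
        "background_distance": spec.background_distance,
        "n_positives": spec.n_positives * len(spec.alleles),
        "n_negatives": spec.n_negatives * len(spec.alleles),
        "n_contaminated": n_contaminated,
        "n_label_flips": n_flipped,
        "true_labels": truth,
        "seed": spec.seed,
    }
    logger.info(
        "planted dataset: %d pHLAs (%d contaminated rows), %d conformations total",
        len(records), n_contaminated,
        sum(len(v) for v in records.values()),
    )
    return PlantedDataset(
        store=MemoryStore(records),
        positives=pd.DataFrame(pos_rows, columns=["peptide", "allele"]),
        negatives=pd.DataFrame(neg_rows, columns=["peptide", "allele", "affinity_nM"]),
        manifest=manifest,
    )
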