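"""Training targets and dataset-preparation logic.

Targets: each surface atom gets a continuous binding score in [0,1] from a
sigmoid of its distance to the nearest ligand heavy atom, so the loss
penalizes mistakes near ligands more than far from them. With several
ligands an atom takes the maximum over ligands.

Dataset preparation mirrors the curation applied to structure databases:
name filters remove water/salt/sugar "ligands", a geometric contact
criterion keeps only bound ligands, composition matching promotes unlabeled
copies of labeled ligands (e.g. the second site of a symmetric dimer), and
multimeric systems are split into single chains except where an interfacial
ligand (within 4 Å of several chains) ties chains together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .types import InvalidInputError, LigandRecord, StructureModel

__all__ = [
    "AtomTargets",
    "LigandFilterPolicy",
    "compute_targets",
    "filter_ligands",
    "augment_duplicate_ligands",
    "split_chains_by_interfacial_ligands",
    "SALT_NAMES",
    "SUGAR_NAMES",
]

SIGMOID_MIDPOINT = 4.0    # Å where target crosses 0.5
SIGMOID_STEEPNESS = 3.0   # Å⁻¹

# common crystallization ions/salts
SALT_NAMES = {
    "NA", "CL", "K", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU", "CO", "NI",
    "CD", "HG", "BR", "IOD", "CS", "LI", "SR", "BA", "AL", "SO4", "PO4",
    "NO3", "CO3", "ACT", "FMT", "CIT", "TAR", "EDO", "GOL", "PEG", "PG4",
}
# common glycan residues
SUGAR_NAMES = {
    "NAG", "NDG", "BMA", "MAN", "GAL", "GLC", "FUC", "XYL", "SIA", "BGC",
    "A2G", "FUL", "RIB", "SUC", "TRE", "MAL", "LAT",
}
from .io import WATER_NAMES  # noqa: E402  (shared name list)


@dataclass
class AtomTargets:
    """Per-surface-atom soft targets, aligned with ``atom_indices``."""

    atom_indices: np.ndarray          # indices into protein_atoms (surface only)
    scores: np.ndarray                # same length, values in [0,1]
    ligand_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.scores < 0) or np.any(self.scores > 1):
            raise InvalidInputError("target scores must lie in [0,1]")

    def write_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"atom_index": self.atom_indices, "target": self.scores}
        ).to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class LigandFilterPolicy:
    excluded_names: frozenset = frozenset(WATER_NAMES | SALT_NAMES | SUGAR_NAMES)
    min_contacts: int = 1
    contact_distance: float = 4.0     # Å

    def __post_init__(self) -> None:
        if not self.excluded_names:
            raise InvalidInputError("excluded-name list must be non-empty")
        if self.contact_distance <= 0:
            raise InvalidInputError("contact distance must be positive")


def compute_targets(
    s: StructureModel,
    ligands: LigandRecord | list[LigandRecord] | None = None,
    midpoint: float = SIGMOID_MIDPOINT,
    steepness: float = SIGMOID_STEEPNESS,
) -> AtomTargets:
    """Sigmoid-of-distance targets for every surface atom.

    target = 1 / (1 + exp(steepness * (d - midpoint))) with d the minimum
    distance to any heavy atom of the ligand; per-atom max over ligands.
    """
    if ligands is None:
        ligands = s.ligands
    if isinstance(ligands, LigandRecord):
        ligands = [ligands]
    surf = s.surface_indices()
    if surf.size == 0:
        raise InvalidInputError("no surface atoms; run detect_surface_atoms first")
    coords = s.coords()[surf]
    scores = np.zeros(len(surf))
    ids = []
    for lig in ligands:
        if not lig.atoms:
            raise InvalidInputError(f"ligand {lig.ligand_id} has no heavy atoms")
        ids.append(lig.ligand_id)
        d, _ = cKDTree(lig.coords()).query(coords)
        scores = np.maximum(scores, 1.0 / (1.0 + np.exp(steepness * (d - midpoint))))
    return AtomTargets(atom_indices=surf, scores=scores, ligand_ids=ids)


def _contact_count(lig: LigandRecord, protein_coords: np.ndarray, cutoff: float) -> int:
    tree = cKDTree(protein_coords)
    return int(sum(len(tree.query_ball_point(c, cutoff)) > 0 for c in lig.coords()))


def filter_ligands(s: StructureModel, policy: LigandFilterPolicy | None = None) -> StructureModel:
    """Drop water/salt/sugar ligands and ligands not in contact with the protein."""
    policy = policy or LigandFilterPolicy()
    pc = s.coords()
    kept = []
    for lig in s.ligands:
        names = {a.residue_name for a in lig.atoms}
        if names & policy.excluded_names:
            continue
        if _contact_count(lig, pc, policy.contact_distance) < policy.min_contacts:
            continue
        kept.append(lig)
    return StructureModel(protein_atoms=s.protein_atoms, ligands=kept, bonds=s.bonds)


def _is_buried(
    lig: LigandRecord,
    protein_coords: np.ndarray,
    min_mean_contacts: float,
    contact_cutoff: float,
) -> bool:
    """Mean per-atom protein heavy-atom contact count over the ligand."""
    tree = cKDTree(protein_coords)
    counts = [len(tree.query_ball_point(c, contact_cutoff)) for c in lig.coords()]
    return float(np.mean(counts)) >= min_mean_contacts


def augment_duplicate_ligands(
    entries: list[tuple[StructureModel, set[str]]],
    min_mean_contacts: float = 5.0,
    contact_cutoff: float = 4.5,
) -> list[set[str]]:
    """Promote unlabeled ligands matching a labeled ligand's composition.

    ``entries`` are (structure, labeled ligand-id set) pairs sharing one PDB
    id. Any unlabeled ligand whose element-composition multiset equals that
    of a labeled ligand anywhere in the entry group, and which is buried
    against its own protein, becomes labeled. Monotone (labels never
    removed) and idempotent.
    """
    labeled_compositions = []
    for s, labels in entries:
        for lig in s.ligands:
            if lig.ligand_id in labels:
                if not lig.atoms:
                    raise InvalidInputError(f"labeled ligand {lig.ligand_id} is empty")
                labeled_compositions.append(lig.composition)
    out = []
    for s, labels in entries:
        new_labels = set(labels)
        pc = s.coords()
        for lig in s.ligands:
            if lig.ligand_id in new_labels:
                continue
            if not lig.atoms:
                raise InvalidInputError(f"ligand {lig.ligand_id} is empty")
            if any(lig.composition == c for c in labeled_compositions) and _is_buried(
                lig, pc, min_mean_contacts, contact_cutoff
            ):
                new_labels.add(lig.ligand_id)
        out.append(new_labels)
    return out


def split_chains_by_interfacial_ligands(
    s: StructureModel, contact: float = 4.0
) -> list[StructureModel]:
    """Split a multimer into subsystems, merging chains that share a ligand.

    A ligand contacts a chain when any of its heavy atoms is within
    ``contact`` Å of a heavy atom of that chain. Chains sharing a ligand end
    up in one subsystem (connected components); every ligand travels with
    exactly one subsystem (its contacted chains, or the nearest chain if it
    touches none).
    """
    chains = sorted({a.chain_id for a in s.protein_atoms})
    chain_atoms = {c: [a for a in s.protein_atoms if a.chain_id == c] for c in chains}
    chain_trees = {
        c: cKDTree(np.array([a.coords for a in atoms]))
        for c, atoms in chain_atoms.items()
    }

    parent = {c: c for c in chains}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    def union(a, b):
        parent[find(a)] = find(b)

    lig_chains: dict[str, list[str]] = {}
    for lig in s.ligands:
        lc = lig.coords()
        touching = [
            c for c in chains
            if min(chain_trees[c].query(lc)[0]) <= contact
        ]
        if not touching:
            nearest = min(chains, key=lambda c: min(chain_trees[c].query(lc)[0]))
            touching = [nearest]
        lig_chains[lig.ligand_id] = touching
        for c in touching[1:]:
            union(touching[0], c)

    groups: dict[str, list[str]] = {}
    for c in chains:
        groups.setdefault(find(c), []).append(c)

    out = []
    for root in sorted(groups):
        members = set(groups[root])
        atoms = [a for c in sorted(members) for a in chain_atoms[c]]
        old_idx = {a.index: k for k, a in enumerate(atoms)}
        reatoms = [_copy_atom(a, old_idx[a.index]) for a in atoms]
        bonds = [
            (min(old_idx[i], old_idx[j]), max(old_idx[i], old_idx[j]), o)
            for i, j, o in s.bonds
            if i in old_idx and j in old_idx
        ]
        ligs = [
            lig for lig in s.ligands if lig_chains[lig.ligand_id][0] in members
        ]
        out.append(StructureModel(protein_atoms=reatoms, ligands=ligs, bonds=bonds))
    return out


def _copy_atom(a, new_index):
    from .types import AtomRecord

    return AtomRecord(
        index=new_index,
        element=a.element,
        atom_name=a.atom_name,
        residue_name=a.residue_name,
        residue_seq=a.residue_seq,
        chain_id=a.chain_id,
        coords=a.coords.copy(),
        formal_charge=a.formal_charge,
        sasa=a.sasa,
        is_surface=a.is_surface,
    )
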