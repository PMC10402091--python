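"""Core in-memory containers for protein structures and near-surface graphs.

Coordinates are in Å everywhere. Only heavy atoms are kept: hydrogens are
dropped at parse time, waters are dropped entirely.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomRecord",
    "LigandRecord",
    "StructureModel",
    "ProteinGraph",
    "InvalidInputError",
]


class InvalidInputError(ValueError):
    """Raised for structurally invalid inputs (empty protein, no surface...)."""


@dataclass
class AtomRecord:
    """One heavy atom of a protein or ligand.

    ``sasa`` and ``is_surface`` are filled in by surface detection and stay
    at their defaults (0.0 / False) until then.
    """

    index: int
    element: str
    atom_name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    formal_charge: int = 0
    sasa: float = 0.0
    is_surface: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise InvalidInputError(
                f"atom {self.index}: coords must be a finite 3-vector"
            )
        self.element = self.element.strip().upper()
        if self.element in ("H", "D"):
            raise InvalidInputError("AtomRecord must be a heavy atom")


@dataclass
class LigandRecord:
    """A bound small molecule: its heavy atoms and element composition."""

    atoms: list[AtomRecord]
    ligand_id: str

    @property
    def composition(self) -> Counter:
        return Counter(a.element for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class StructureModel:
    """Parsed protein heavy atoms plus any bound ligands.

    ``bonds`` maps covalent bonds between protein atoms as
    ``(i, j, order)`` with ``i < j`` indices into ``protein_atoms`` and order
    1/2/3 or 1.5 for aromatic.
    """

    protein_atoms: list[AtomRecord]
    ligands: list[LigandRecord] = field(default_factory=list)
    bonds: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.protein_atoms)
        idx = [a.index for a in self.protein_atoms]
        if idx != list(range(n)):
            raise InvalidInputError("protein atom indices must be 0..n-1")
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise InvalidInputError(f"bond ({i},{j}) references missing atom")

    @property
    def n_atoms(self) -> int:
        return len(self.protein_atoms)

    def coords(self) -> np.ndarray:
        if not self.protein_atoms:
            return np.zeros((0, 3))
        return np.array([a.coords for a in self.protein_atoms], dtype=float)

    def surface_indices(self) -> np.ndarray:
        return np.array(
            [a.index for a in self.protein_atoms if a.is_surface], dtype=int
        )

    def bond_orders(self) -> dict[tuple[int, int], float]:
        """Symmetric lookup of covalent bond orders between protein atoms."""
        table: dict[tuple[int, int], float] = {}
        for i, j, order in self.bonds:
            table[(i, j)] = order
            table[(j, i)] = order
        return table

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly moved copy (protein and ligands move together)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)

        def move(a: AtomRecord) -> AtomRecord:
            return AtomRecord(
                index=a.index,
                element=a.element,
                atom_name=a.atom_name,
                residue_name=a.residue_name,
                residue_seq=a.residue_seq,
                chain_id=a.chain_id,
                coords=rotation @ a.coords + translation,
                formal_charge=a.formal_charge,
                sasa=a.sasa,
                is_surface=a.is_surface,
            )

        return StructureModel(
            protein_atoms=[move(a) for a in self.protein_atoms],
            ligands=[
                LigandRecord(atoms=[move(a) for a in lig.atoms], ligand_id=lig.ligand_id)
                for lig in self.ligands
            ],
            bonds=list(self.bonds),
        )


@dataclass
class ProteinGraph:
    """Near-surface graph: surface atoms plus buried atoms within one hop.

    Nodes back-map to ``StructureModel.protein_atoms`` through
    ``node_atom_index``. ``edge_index`` holds directed edges (both
    orientations of every pair); ``edge_features`` columns are
    (inverse distance Å⁻¹, bond order, covalent flag). Node features carry no
    coordinate information, so the graph representation is invariant under
    rigid motion.
    """

    node_atom_index: np.ndarray          # (n_nodes,) int
    node_coords: np.ndarray              # (n_nodes, 3) float — for clustering only
    edge_index: np.ndarray               # (2, n_edges) int, directed
    edge_features: np.ndarray            # (n_edges, 3) float
    surface_mask: np.ndarray             # (n_nodes,) bool
    node_features: np.ndarray | None = None   # (n_nodes, n_feat) float
    feature_schema: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_atom_index)

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def save_npz(self, path) -> None:
        np.savez(
            path,
            node_atom_index=self.node_atom_index,
            node_coords=self.node_coords,
            edge_index=self.edge_index,
            edge_features=self.edge_features,
            surface_mask=self.surface_mask,
            node_features=(
                self.node_features if self.node_features is not None else np.zeros((0, 0))
            ),
            feature_schema=np.array(self.feature_schema or ""),
        )

    @classmethod
    def load_npz(cls, path) -> "ProteinGraph":
        d = np.load(path, allow_pickle=False)
        feats = d["node_features"]
        schema = str(d["feature_schema"])
        return cls(
            node_atom_index=d["node_atom_index"],
            node_coords=d["node_coords"],
            edge_index=d["edge_index"],
            edge_features=d["edge_features"],
            surface_mask=d["surface_mask"],
            node_features=None if feats.size == 0 else feats,
            feature_schema=schema or None,
        )
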