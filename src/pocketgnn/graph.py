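"""Near-surface graph construction and rotation-invariant featurization.

The graph scored by the network is the induced subgraph on surface atoms
plus buried atoms within one edge-cutoff (5 Å default) of a surface atom.
Node features are purely chemical (element, charge, degree, aromaticity,
residue identity, backbone flag) — coordinates never enter, which makes the
whole pipeline exactly invariant under rigid motion. Edge features are
inverse distance, bond order and a covalent flag.

Also provides the fixed distance-weighted message pass used by surface-point
methods (weights w(d) = 1 - d/r within radius r), both as a standalone
featurizer and as the frozen-attention reference the attention layer must
reduce to.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import cKDTree

from .io import STANDARD_AMINO_ACIDS
from .types import InvalidInputError, ProteinGraph, StructureModel

__all__ = [
    "FEATURE_SCHEMA",
    "FeatureSchema",
    "build_near_surface_graph",
    "featurize_nodes",
    "featurize_edges",
    "featurize",
    "p2rank_reference_featurize",
]

GRAPH_CUTOFF = 5.0          # Å, edge and buried-atom inclusion cutoff
P2RANK_RADIUS = 6.0         # Å, fixed-featurizer neighbourhood
MIN_ATOM_SEPARATION = 0.01  # Å, coincident-atom guard

ELEMENT_VOCAB = ["C", "N", "O", "S", "P"]          # + OTHER
RESIDUE_VOCAB = sorted(STANDARD_AMINO_ACIDS)       # + OTHER
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

# aromatic ring atoms of the standard aromatic residues, by atom name
AROMATIC_RING_ATOMS = {
    "PHE": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TYR": {"CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"},
    "HIS": {"CG", "ND1", "CD2", "CE1", "NE2"},
}


class FeatureSchema:
    """Named, versioned layout of the node feature vector.

    Columns can be appended in later versions without breaking serialized
    checkpoints, which refuse to load across schema versions.
    """

    version = "atom-residue-v1"

    def __init__(self) -> None:
        self.columns: list[str] = (
            [f"element_{e}" for e in ELEMENT_VOCAB]
            + ["element_OTHER", "formal_charge", "degree", "aromatic"]
            + [f"residue_{r}" for r in RESIDUE_VOCAB]
            + ["residue_OTHER", "backbone"]
        )
        # channels that are genuinely numeric (targets for input noise);
        # one-hot and flag channels are left clean
        self.continuous_columns = ["formal_charge", "degree"]

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def continuous_mask(self) -> np.ndarray:
        return np.array([c in self.continuous_columns for c in self.columns])


FEATURE_SCHEMA = FeatureSchema()


def build_near_surface_graph(s: StructureModel, cutoff: float = GRAPH_CUTOFF) -> ProteinGraph:
    """Induced graph on surface atoms plus buried atoms within ``cutoff``.

    Edges connect every node pair within ``cutoff`` Å (both directions).
    Raises :class:`InvalidInputError` when the structure has no surface atom.
    """
    surf_idx = s.surface_indices()
    if surf_idx.size == 0:
        raise InvalidInputError("no surface atoms; run detect_surface_atoms first")
    coords = s.coords()
    tree = cKDTree(coords)
    near = tree.query_ball_point(coords[surf_idx], cutoff)
    keep = set(surf_idx.tolist())
    for lst in near:
        keep.update(lst)
    node_atom_index = np.array(sorted(keep), dtype=int)
    node_coords = coords[node_atom_index]
    surface_mask = np.array(
        [s.protein_atoms[i].is_surface for i in node_atom_index], dtype=bool
    )
    sub = cKDTree(node_coords)
    pairs = sorted(sub.query_pairs(cutoff))
    if pairs:
        pa = np.array(pairs, dtype=int).T
        edge_index = np.concatenate([pa, pa[::-1]], axis=1)
    else:
        edge_index = np.zeros((2, 0), dtype=int)
    g = ProteinGraph(
        node_atom_index=node_atom_index,
        node_coords=node_coords,
        edge_index=edge_index,
        edge_features=np.zeros((edge_index.shape[1], 3)),
        surface_mask=surface_mask,
    )
    return g


def _atom_degrees(s: StructureModel) -> np.ndarray:
    deg = np.zeros(s.n_atoms)
    for i, j, _ in s.bonds:
        deg[i] += 1
        deg[j] += 1
    return deg


def _aromatic_flags(s: StructureModel) -> np.ndarray:
    flags = np.zeros(s.n_atoms)
    order = s.bond_orders()
    ar_bonded = {i for (i, j), o in order.items() if o == 1.5}
    for a in s.protein_atoms:
        ring = AROMATIC_RING_ATOMS.get(a.residue_name)
        if (ring and a.atom_name in ring) or a.index in ar_bonded:
            flags[a.index] = 1.0
    return flags


def featurize_nodes(s: StructureModel, g: ProteinGraph) -> ProteinGraph:
    """Fill ``g.node_features`` with the schema's chemical feature vector."""
    schema = FEATURE_SCHEMA
    deg = _atom_degrees(s)
    aromatic = _aromatic_flags(s)
    feats = np.zeros((g.n_nodes, schema.n_features))
    n_elem = len(ELEMENT_VOCAB)
    res_offset = n_elem + 4  # element onehot + OTHER + charge + degree + aromatic... see below
    # layout: elements(5), element_OTHER, formal_charge, degree, aromatic,
    #         residues(20), residue_OTHER, backbone
    for row, ai in enumerate(g.node_atom_index):
        a = s.protein_atoms[ai]
        try:
            feats[row, ELEMENT_VOCAB.index(a.element)] = 1.0
        except ValueError:
            feats[row, n_elem] = 1.0
        feats[row, n_elem + 1] = a.formal_charge
        feats[row, n_elem + 2] = deg[ai]
        feats[row, n_elem + 3] = aromatic[ai]
        try:
            feats[row, res_offset + RESIDUE_VOCAB.index(a.residue_name)] = 1.0
        except ValueError:
            feats[row, res_offset + len(RESIDUE_VOCAB)] = 1.0
        if a.atom_name in BACKBONE_ATOMS and a.residue_name in STANDARD_AMINO_ACIDS:
            feats[row, -1] = 1.0
    g.node_features = feats
    g.feature_schema = schema.version
    return g


def featurize_edges(s: StructureModel, g: ProteinGraph) -> ProteinGraph:
    """Edge features: (1/d in Å⁻¹, bond order, covalent flag), symmetric."""
    order = s.bond_orders()
    src, dst = g.edge_index
    diffs = g.node_coords[src] - g.node_coords[dst]
    d = np.linalg.norm(diffs, axis=1)
    if np.any(d < MIN_ATOM_SEPARATION):
        k = int(np.argmin(d))
        raise InvalidInputError(
            f"coincident atoms: nodes {src[k]} and {dst[k]} are {d[k]:.4f} Å apart"
        )
    feats = np.zeros((g.n_edges, 3))
    feats[:, 0] = 1.0 / d
    for e in range(g.n_edges):
        o = order.get((int(g.node_atom_index[src[e]]), int(g.node_atom_index[dst[e]])))
        if o is not None:
            feats[e, 1] = o
            feats[e, 2] = 1.0
    g.edge_features = feats
    return g


def featurize(s: StructureModel, g: ProteinGraph) -> ProteinGraph:
    return featurize_edges(s, featurize_nodes(s, g))


def p2rank_reference_featurize(
    points: np.ndarray,
    s: StructureModel,
    g: ProteinGraph,
    radius: float = P2RANK_RADIUS,
) -> np.ndarray:
    """Fixed distance-weighted average of nearby atom features.

    For each query point i, x'_i = Σ_j α_ij x_j over graph atoms j within
    ``radius``, with α_ij = w(d_ij)/Σ_k w(d_ik) and w(d) = 1 - d/radius.
    Points with no atom in range get a zero vector and a warning.
    """
    if g.node_features is None:
        raise InvalidInputError("node features not computed")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(g.node_coords)
    out = np.zeros((len(points), g.node_features.shape[1]))
    for i, p in enumerate(points):
        neigh = tree.query_ball_point(p, radius)
        if not neigh:
            warnings.warn(f"point {i} has no atoms within {radius} Å; zero features")
            continue
        nb = np.asarray(neigh)
        d = np.linalg.norm(g.node_coords[nb] - p[None, :], axis=1)
        w = 1.0 - d / radius
        total = w.sum()
        if total <= 0:
            warnings.warn(f"point {i}: all weights vanish at the radius boundary")
            continue
        out[i] = (w / total) @ g.node_features[nb]
    return out
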