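"""Seeded generators of synthetic protein-like structures with known pockets.

These scenes stand in for curated protein–ligand databases so the whole
pipeline is testable without downloads. A toy protein is a globular cloud
of 4-atom residues (N, CA, C, O on a jittered lattice) with real amino-acid
names, chain ids and explicit backbone bonds. A pocket scene carves a
concave invagination into the blob, drops a small ring-shaped ligand inside
at a controlled contact distance, and reports the ground-truth pocket atoms
(surface atoms strictly within the target-sigmoid midpoint of the ligand,
so ground truth coincides exactly with target score > 0.5).

Pocket-lining residues are drawn from a binding-prone amino-acid subset
(aromatic/polar) with high probability; elsewhere the background set is
used. This gives the purely chemical featurization a learnable signal
— synthetic scenes are labelled ``synthetic`` by construction and make no
claim of conformational realism.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .io import write_structure  # re-exported: fixtures own the writers' contract
from .labeling import SIGMOID_MIDPOINT
from .surface import detect_surface_atoms
from .types import AtomRecord, LigandRecord, StructureModel

__all__ = ["SceneSpec", "make_toy_protein", "make_pocket_scene", "write_structure", "write_manifest"]

ATOM_SPACING = 2.2      # Å between lattice atoms (dense enough to bury a core)
JITTER = 0.25           # Å uniform jitter per atom
MIN_SEPARATION = 1.2    # Å guaranteed minimum interatomic distance

_RESIDUE_ATOM_NAMES = ["N", "CA", "C", "O"]  # four heavy atoms per toy residue

POCKET_RESIDUES = ["HIS", "ASP", "GLU", "SER", "TYR", "TRP", "PHE", "ASN"]
BACKGROUND_RESIDUES = ["ALA", "LEU", "VAL", "ILE", "GLY", "PRO", "LYS", "ARG", "THR", "MET"]

_LIGAND_ELEMENTS = ["C", "N", "C", "O"]  # cycled


@dataclass
class SceneSpec:
    n_residues: int = 24
    pocket_depth: float = 3.0        # Å, how deep the invagination is carved
    ligand_size: int = 6             # heavy atoms
    arrangement: str = "monomer"     # monomer | dimer | dimer_interfacial | trimer
    seed: int = 0
    carve_radius: float = 4.0        # Å, atoms this close to the pocket point are removed
    enrich_radius: float = 6.5       # Å, pocket-lining residue-name enrichment
    enrich_prob: float = 0.8
    gt_radius: float = SIGMOID_MIDPOINT  # ground-truth pocket radius (strict <)


def _lattice_atoms(n: int, rng: np.random.Generator) -> np.ndarray:
    """First ``n`` jittered lattice points inside a ball, serpentine order,
    so consecutive points (and hence residues) are spatially contiguous."""
    r = 2.0
    while True:
        k = int(np.ceil(r / ATOM_SPACING))
        axes = np.arange(-k, k + 1) * ATOM_SPACING
        grid = np.array(np.meshgrid(axes, axes, axes)).reshape(3, -1).T
        grid = grid[np.linalg.norm(grid, axis=1) <= r]
        if len(grid) >= n:
            break
        r += ATOM_SPACING / 2
    # serpentine: z-slabs, snake along y, then x
    order = np.lexsort(
        (grid[:, 0] * np.where(np.round(grid[:, 1]) % 2 == 0, 1, -1), grid[:, 1], grid[:, 2])
    )
    pts = grid[order][:n].astype(float)
    pts += rng.uniform(-JITTER, JITTER, size=pts.shape)
    return pts


def _build_residues(
    coords: np.ndarray,
    residue_names: list[str],
    chain_id: str,
    start_seq: int = 1,
) -> tuple[list[AtomRecord], list[tuple[int, int, float]]]:
    """Group consecutive atoms into 4-atom residues with chain bonds."""
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int, float]] = []
    n_per = len(_RESIDUE_ATOM_NAMES)
    for idx, xyz in enumerate(coords):
        r = idx // n_per
        atom_name = _RESIDUE_ATOM_NAMES[idx % n_per]
        atoms.append(
            AtomRecord(
                index=idx,
                element=atom_name[0],
                atom_name=atom_name,
                residue_name=residue_names[r],
                residue_seq=start_seq + r,
                chain_id=chain_id,
                coords=xyz,
            )
        )
        if idx > 0:
            bonds.append((idx - 1, idx, 1.0))
    return atoms, bonds


def make_toy_protein(spec: SceneSpec) -> StructureModel:
    """Globular toy protein: ``n_residues`` 4-atom residues, one chain."""
    rng = np.random.default_rng(spec.seed)
    coords = _lattice_atoms(spec.n_residues * len(_RESIDUE_ATOM_NAMES), rng)
    names = [str(rng.choice(BACKGROUND_RESIDUES)) for _ in range(spec.n_residues)]
    atoms, bonds = _build_residues(coords, names, "A")
    return StructureModel(protein_atoms=atoms, ligands=[], bonds=bonds)


def _ring_ligand(
    center: np.ndarray, n_atoms: int, rng: np.random.Generator, lig_id: str, seq: int
) -> LigandRecord:
    radius = max(1.3, 1.3 / (2 * np.sin(np.pi / max(n_atoms, 3))))
    # random ring orientation
    q = rng.normal(size=(3, 3))
    u, _ = np.linalg.qr(q)
    angles = 2 * np.pi * np.arange(n_atoms) / n_atoms
    pts = np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n_atoms)]
    ) @ u.T + center
    atoms = [
        AtomRecord(
            index=k,
            element=_LIGAND_ELEMENTS[k % len(_LIGAND_ELEMENTS)],
            atom_name=f"{_LIGAND_ELEMENTS[k % len(_LIGAND_ELEMENTS)]}{k + 1}",
            residue_name="LIG",
            residue_seq=seq,
            chain_id="X",
            coords=pts[k],
        )
        for k in range(n_atoms)
    ]
    return LigandRecord(atoms=atoms, ligand_id=lig_id)


def _adjust_ligand_contact(
    lig: LigandRecord, protein_coords: np.ndarray, lo: float = 2.4, hi: float = 3.6
) -> None:
    """Translate the ligand so its closest protein contact lies in [lo, hi] Å."""
    for _ in range(40):
        lc = lig.coords()
        tree = cKDTree(protein_coords)
        d, j = tree.query(lc)
        k = int(np.argmin(d))
        dmin = d[k]
        if lo <= dmin <= hi:
            return
        direction = protein_coords[j[k]] - lc[k]
        direction /= np.linalg.norm(direction)
        shift = (dmin - 0.5 * (lo + hi)) * direction
        for a in lig.atoms:
            a.coords = a.coords + shift
    raise RuntimeError("could not place ligand at the requested contact distance")


def _carved_pocket_chain(
    spec: SceneSpec, rng: np.random.Generator, chain_id: str
) -> tuple[list[AtomRecord], list[tuple[int, int, float]], LigandRecord]:
    n_per = len(_RESIDUE_ATOM_NAMES)
    coords = _lattice_atoms((spec.n_residues + 10) * n_per, rng)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    blob_radius = np.linalg.norm(coords, axis=1).max()
    pocket_point = direction * (blob_radius - spec.pocket_depth)
    keep = np.linalg.norm(coords - pocket_point, axis=1) > spec.carve_radius
    coords = coords[keep]
    n_res = int(np.ceil(len(coords) / n_per))
    # residue-name enrichment near the pocket mouth
    names = []
    for r in range(n_res):
        block = coords[r * n_per : (r + 1) * n_per]
        dd = float(np.linalg.norm(block.mean(axis=0) - pocket_point))
        if dd <= spec.enrich_radius and rng.random() < spec.enrich_prob:
            names.append(str(rng.choice(POCKET_RESIDUES)))
        else:
            names.append(str(rng.choice(BACKGROUND_RESIDUES)))
    atoms, bonds = _build_residues(coords, names, chain_id)
    lig = _ring_ligand(pocket_point, spec.ligand_size, rng, f"LIG_{chain_id}", 1)
    _adjust_ligand_contact(lig, coords)
    return atoms, bonds, lig


def _shift_atoms(atoms, bonds, lig, offset, index0, chain_id, rotation=None):
    rot = rotation if rotation is not None else np.eye(3)
    out_atoms = []
    for a in atoms:
        out_atoms.append(
            AtomRecord(
                index=index0 + a.index,
                element=a.element,
                atom_name=a.atom_name,
                residue_name=a.residue_name,
                residue_seq=a.residue_seq,
                chain_id=chain_id,
                coords=rot @ a.coords + offset,
            )
        )
    out_bonds = [(index0 + i, index0 + j, o) for i, j, o in bonds]
    out_lig = None
    if lig is not None:
        out_lig = LigandRecord(
            atoms=[
                AtomRecord(
                    index=a.index,
                    element=a.element,
                    atom_name=a.atom_name,
                    residue_name=a.residue_name,
                    residue_seq=a.residue_seq,
                    chain_id=chain_id,
                    coords=rot @ a.coords + offset,
                )
                for a in lig.atoms
            ],
            ligand_id=f"{lig.ligand_id}_{chain_id}",
        )
    return out_atoms, out_bonds, out_lig


def make_pocket_scene(spec: SceneSpec) -> tuple[StructureModel, np.ndarray]:
    """Build a scene with ligand(s) in concave pockets.

    Returns ``(structure, ground_truth)`` where ``ground_truth`` holds the
    indices of surface atoms strictly within ``spec.gt_radius`` of any
    ligand heavy atom. Surface flags are already computed on the returned
    structure. Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    atoms, bonds, lig = _carved_pocket_chain(spec, rng, "A")
    ligands = [lig]

    if spec.arrangement in ("dimer", "dimer_interfacial", "trimer"):
        flip = np.diag([1.0, -1.0, -1.0])  # 180° about x
        n_copies = 2 if spec.arrangement == "trimer" else 1
        gap = 7.0 if spec.arrangement == "dimer_interfacial" else 14.0
        all_atoms = list(atoms)
        all_bonds = list(bonds)
        for c in range(n_copies):
            chain_id = chr(ord("B") + c)
            rng2 = np.random.default_rng(spec.seed + 7 * (c + 1))
            atoms2, bonds2, lig2 = _carved_pocket_chain(spec, rng2, chain_id)
            placed = np.array([a.coords for a in all_atoms])
            extent = placed[:, 0].max() - np.array([a.coords for a in atoms2])[:, 0].min()
            offset = np.array([extent + gap, 0.0, 0.0])
            # correct the x-offset so the true minimum inter-chain gap is `gap`
            for _ in range(3):
                moved = np.array([flip @ a.coords + offset for a in atoms2])
                lig_moved = np.array([flip @ a.coords + offset for a in lig2.atoms])
                g = min(
                    cKDTree(placed).query(moved)[0].min(),
                    cKDTree(placed).query(lig_moved)[0].min(),
                )
                if abs(g - gap) < 0.1:
                    break
                offset[0] += gap - g
            atoms2, bonds2, lig2 = _shift_atoms(
                atoms2, bonds2, lig2, offset, len(all_atoms), chain_id, flip
            )
            all_atoms += atoms2
            all_bonds += bonds2
            ligands.append(lig2)
        atoms, bonds = all_atoms, all_bonds
        if spec.arrangement == "dimer_interfacial":
            # replace the per-chain ligands with one ligand bridging the
            # interface: ring plane contains the inter-chain axis so the
            # ligand reaches toward both chains, then balance the contacts
            a_coords = np.array([a.coords for a in atoms if a.chain_id == "A"])
            b_coords = np.array([a.coords for a in atoms if a.chain_id == "B"])
            ta, tb = cKDTree(a_coords), cKDTree(b_coords)
            d, j = ta.query(b_coords)
            kb = int(np.argmin(d))
            pa, pb = a_coords[j[kb]], b_coords[kb]
            axis = (pb - pa) / np.linalg.norm(pb - pa)
            perp = np.cross(axis, [0.0, 0.0, 1.0])
            if np.linalg.norm(perp) < 1e-6:
                perp = np.cross(axis, [0.0, 1.0, 0.0])
            perp /= np.linalg.norm(perp)
            radius = max(1.3, 1.3 / (2 * np.sin(np.pi / max(spec.ligand_size, 3))))
            angles = 2 * np.pi * np.arange(spec.ligand_size) / spec.ligand_size
            center = 0.5 * (pa + pb)
            pts = center + radius * (
                np.outer(np.cos(angles), axis) + np.outer(np.sin(angles), perp)
            )
            ilig = LigandRecord(
                atoms=[
                    AtomRecord(
                        index=k,
                        element=_LIGAND_ELEMENTS[k % len(_LIGAND_ELEMENTS)],
                        atom_name=f"{_LIGAND_ELEMENTS[k % len(_LIGAND_ELEMENTS)]}{k + 1}",
                        residue_name="LIG",
                        residue_seq=1,
                        chain_id="X",
                        coords=pts[k],
                    )
                    for k in range(spec.ligand_size)
                ],
                ligand_id="LIG_IF",
            )
            for _ in range(20):  # balance contacts to both chains
                lc = ilig.coords()
                da = ta.query(lc)[0].min()
                db = tb.query(lc)[0].min()
                if abs(da - db) < 0.1:
                    break
                shift = 0.5 * (da - db) * axis
                for a in ilig.atoms:
                    a.coords = a.coords + shift
            lc = ilig.coords()
            da, db = ta.query(lc)[0].min(), tb.query(lc)[0].min()
            if not (1.25 <= da < 4.0 and 1.25 <= db < 4.0):
                raise RuntimeError(
                    f"interfacial ligand placement failed (dA={da:.2f}, dB={db:.2f})"
                )
            ligands = [ilig]

    s = StructureModel(protein_atoms=atoms, ligands=ligands, bonds=bonds)
    detect_surface_atoms(s)
    coords = s.coords()
    gt: set[int] = set()
    for lg in s.ligands:
        tree = cKDTree(lg.coords())
        d, _ = tree.query(coords)
        for i in np.flatnonzero((d < spec.gt_radius)):
            if s.protein_atoms[i].is_surface:
                gt.add(int(i))
    return s, np.array(sorted(gt), dtype=int)


def write_manifest(specs: list[SceneSpec], path) -> None:
    """Record the seeds and parameters of a generated fixture set."""
    Path(path).write_text(json.dumps([asdict(sp) for sp in specs], indent=2))


def read_manifest(path) -> list[SceneSpec]:
    return [SceneSpec(**d) for d in json.loads(Path(path).read_text())]
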