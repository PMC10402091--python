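"""Structure readers and writers (PDB and TRIPOS mol2).

PDB files go through :mod:`gemmi`. mol2 support is a minimal in-package
reader/writer for the ATOM/BOND sections, since no installed library offers
a dependable mol2 round trip for arbitrary structures.

Parsing rules
-------------
* hydrogens (H/D) are dropped everywhere;
* waters are dropped entirely (neither protein nor ligand);
* PDB: ATOM records become protein atoms, non-water HETATM records become
  ligands grouped per residue; altloc duplicates keep the highest occupancy
  (ties: first in file);
* mol2: residues with standard amino-acid names become protein, everything
  else a ligand;
* covalent bonds between protein atoms come from the file when present
  (mol2 BOND section) and are otherwise inferred with an element-pair
  distance rule at order 1.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .types import AtomRecord, InvalidInputError, LigandRecord, StructureModel

__all__ = ["parse_structure", "write_structure", "ParseError", "WATER_NAMES"]


class ParseError(ValueError):
    pass


WATER_NAMES = {"HOH", "WAT", "DOD", "H2O", "TIP", "TIP3", "SOL"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# single-bond covalent radii (Å); pairs bond when d < 1.3 * (r_i + r_j)
COVALENT_RADII = {
    "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "F": 0.57,
    "CL": 1.02, "BR": 1.20, "I": 1.39, "B": 0.84, "SE": 1.20,
}
_BOND_SCALE = 1.3

_MOL2_ORDER = {"1": 1.0, "2": 2.0, "3": 3.0, "am": 1.0, "ar": 1.5, "du": 1.0}
_ORDER_MOL2 = {1.0: "1", 2.0: "2", 3.0: "3", 1.5: "ar"}


def infer_covalent_bonds(atoms: list[AtomRecord]) -> list[tuple[int, int, float]]:
    """Distance-rule single bonds between heavy atoms (order fixed at 1)."""
    if len(atoms) < 2:
        return []
    coords = np.array([a.coords for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, 0.77) for a in atoms])
    tree = cKDTree(coords)
    max_cut = _BOND_SCALE * 2 * radii.max()
    bonds = []
    for i, j in sorted(tree.query_pairs(max_cut)):
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < _BOND_SCALE * (radii[i] + radii[j]):
            bonds.append((i, j, 1.0))
    return bonds


def _finalize(protein_raw, ligand_groups, protein_bonds_raw) -> StructureModel:
    """Reindex protein atoms 0..n-1, remap bonds, build ligand records."""
    if not protein_raw:
        raise InvalidInputError("structure contains no protein heavy atoms")
    remap = {}
    atoms = []
    for new_idx, (old_idx, a) in enumerate(protein_raw):
        remap[old_idx] = new_idx
        a.index = new_idx
        atoms.append(a)
    if protein_bonds_raw is None:
        bonds = infer_covalent_bonds(atoms)
    else:
        bonds = [
            (remap[i], remap[j], o)
            for i, j, o in protein_bonds_raw
            if i in remap and j in remap
        ]
        bonds = [(min(i, j), max(i, j), o) for i, j, o in bonds]
    ligands = []
    for lig_id, lig_atoms in ligand_groups.items():
        for k, a in enumerate(lig_atoms):
            a.index = k
        ligands.append(LigandRecord(atoms=lig_atoms, ligand_id=lig_id))
    return StructureModel(protein_atoms=atoms, ligands=ligands, bonds=bonds)


def _parse_pdb(path: Path) -> StructureModel:
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise InvalidInputError(f"{path}: no models in file")
    model = st[0]  # multi-model files: model 1 only

    protein_raw: list[tuple[int, AtomRecord]] = []
    ligand_groups: dict[str, list[AtomRecord]] = {}
    counter = 0
    for chain in model:
        for residue in chain:
            resname = residue.name.strip().upper()
            if resname in WATER_NAMES:
                continue
            is_het = residue.het_flag == "H"
            # altloc: per atom name keep the highest occupancy, tie -> first
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.element.name.upper() in ("H", "D"):
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ + 1e-9:
                    best[atom.name] = atom
            for atom in best.values():
                rec = AtomRecord(
                    index=counter,
                    element=atom.element.name.upper() or "C",
                    atom_name=atom.name,
                    residue_name=resname,
                    residue_seq=residue.seqid.num,
                    chain_id=chain.name,
                    coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    formal_charge=int(atom.charge),
                )
                if is_het:
                    key = f"{resname}_{chain.name}_{residue.seqid.num}"
                    ligand_groups.setdefault(key, []).append(rec)
                else:
                    protein_raw.append((counter, rec))
                counter += 1
    return _finalize(protein_raw, ligand_groups, None)


def _parse_mol2(path: Path) -> StructureModel:
    lines = path.read_text().splitlines()
    section = None
    atoms_raw: dict[int, tuple[AtomRecord, str]] = {}  # file id -> (record, resname)
    bonds_raw: list[tuple[int, int, float]] = []
    for lineno, line in enumerate(lines, 1):
        stripped = line.strip()
        if stripped.startswith("@<TRIPOS>"):
            section = stripped[9:].upper()
            continue
        if not stripped or stripped.startswith("#"):
            continue
        if section == "ATOM":
            parts = stripped.split()
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: malformed ATOM line")
            try:
                aid = int(parts[0])
                name = parts[1]
                x, y, z = (float(parts[2]), float(parts[3]), float(parts[4]))
                sybyl = parts[5]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            subst_name = parts[7] if len(parts) > 7 else "UNK1"
            charge = float(parts[8]) if len(parts) > 8 else 0.0
            element = sybyl.split(".")[0].upper()
            if element in ("H", "D"):
                continue
            resname = "".join(c for c in subst_name if not c.isdigit()).upper() or "UNK"
            digits = "".join(c for c in subst_name if c.isdigit())
            resseq = int(digits) if digits else int(parts[6]) if len(parts) > 6 else 1
            if resname in WATER_NAMES:
                continue
            rec = AtomRecord(
                index=aid,
                element=element,
                atom_name=name,
                residue_name=resname,
                residue_seq=resseq,
                chain_id="A",
                coords=np.array([x, y, z]),
                formal_charge=int(round(charge)),
            )
            atoms_raw[aid] = (rec, resname)
        elif section == "BOND":
            parts = stripped.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: malformed BOND line")
            try:
                i, j = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            order = _MOL2_ORDER.get(parts[3].lower(), 1.0)
            bonds_raw.append((i, j, order))

    protein_raw = []
    ligand_groups: dict[str, list[AtomRecord]] = {}
    for aid in sorted(atoms_raw):
        rec, resname = atoms_raw[aid]
        if resname in STANDARD_AMINO_ACIDS:
            protein_raw.append((aid, rec))
        else:
            key = f"{resname}_{rec.residue_seq}"
            ligand_groups.setdefault(key, []).append(rec)
    return _finalize(protein_raw, ligand_groups, bonds_raw)


def parse_structure(path, format: str | None = None) -> StructureModel:
    """Read a PDB or mol2 file into a :class:`StructureModel`.

    ``format`` is ``"pdb"`` or ``"mol2"``; inferred from the suffix when
    omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        return _parse_pdb(path)
    if fmt == "mol2":
        return _parse_mol2(path)
    raise ValueError(f"unsupported format {fmt!r} (expected pdb or mol2)")


def _to_gemmi(s: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "pocketgnn"
    model = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def add_atom(rec: AtomRecord, het: bool) -> None:
        chain = chains.get(rec.chain_id)
        if chain is None:
            chain = gemmi.Chain(rec.chain_id)
            chains[rec.chain_id] = chain
            model.add_chain(chain)
            chain = model[len(model) - 1]
            chains[rec.chain_id] = chain
        res = None
        if len(chain) > 0:
            last = chain[len(chain) - 1]
            if last.seqid.num == rec.residue_seq and last.name == rec.residue_name:
                res = last
        if res is None:
            r = gemmi.Residue()
            r.name = rec.residue_name
            r.seqid = gemmi.SeqId(rec.residue_seq, " ")
            r.het_flag = "H" if het else "A"
            chain.add_residue(r)
            res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = rec.atom_name
        atom.element = gemmi.Element(rec.element.capitalize())
        atom.pos = gemmi.Position(*rec.coords)
        atom.occ = 1.0
        atom.charge = rec.formal_charge
        res.add_atom(atom)

    for rec in s.protein_atoms:
        add_atom(rec, het=False)
    for lig in s.ligands:
        for rec in lig.atoms:
            add_atom(rec, het=True)
    st.add_model(model)
    st.setup_entities()
    return st


def _write_mol2(s: StructureModel, path: Path) -> None:
    atom_lines = []
    serial = {}
    n = 0
    subst_id = 0
    last_res = None
    all_atoms: list[tuple[AtomRecord, str]] = [
        (a, f"{a.residue_name}{a.residue_seq}") for a in s.protein_atoms
    ]
    for lig in s.ligands:
        for a in lig.atoms:
            all_atoms.append((a, f"{a.residue_name}{a.residue_seq}"))
    for a, subst in all_atoms:
        n += 1
        serial[id(a)] = n
        if subst != last_res:
            subst_id += 1
            last_res = subst
        atom_lines.append(
            f"{n:>7d} {a.atom_name:<8s}{a.coords[0]:>10.4f}{a.coords[1]:>10.4f}"
            f"{a.coords[2]:>10.4f} {a.element.capitalize():<6s}"
            f"{subst_id:>4d} {subst:<8s}{float(a.formal_charge):>8.4f}"
        )
    bond_lines = []
    for k, (i, j, order) in enumerate(s.bonds, 1):
        si = serial[id(s.protein_atoms[i])]
        sj = serial[id(s.protein_atoms[j])]
        bond_lines.append(f"{k:>6d}{si:>6d}{sj:>6d} {_ORDER_MOL2.get(order, '1')}")
    text = "\n".join(
        [
            "@<TRIPOS>MOLECULE",
            "pocketgnn",
            f"{len(atom_lines):>5d}{len(bond_lines):>6d}     0     0     0",
            "PROTEIN",
            "NO_CHARGES",
            "",
            "@<TRIPOS>ATOM",
            *atom_lines,
            "@<TRIPOS>BOND",
            *bond_lines,
            "",
        ]
    )
    path.write_text(text)


def write_structure(s: StructureModel, path, format: str | None = None) -> None:
    """Write a structure as PDB (via gemmi, hybrid-36 serials past 99999
    handled by the library) or mol2."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "pdb":
        st = _to_gemmi(s)
        st.write_pdb(str(path))
    elif fmt == "mol2":
        _write_mol2(s, path)
    else:
        raise ValueError(f"unsupported format {fmt!r} (expected pdb or mol2)")
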