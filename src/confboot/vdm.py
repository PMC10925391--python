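"""Van der Mer-inspired synthetic complex extraction.

A van der Mer (vdM) is an amino acid whose sidechain packs against residues
far away in the 1-D sequence — geometrically, a good mimic of a noncovalent
protein-ligand interaction.  This module scans a crystal structure for
sidechains with many sequence-distant heavy-atom contacts, treats the best
ones as surrogate "ligands", deletes them (plus their sequence-local
neighbors, to open a pocket-shaped hole) from the receptor, and writes out a
receptor/ligand/pocket triple usable as a synthetic docked complex.

Parsing and PDB output go through gemmi; the ligand SDF (with single bonds
perceived from covalent distances) goes through RDKit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueRef",
    "Structure",
    "VdmCandidate",
    "SyntheticComplex",
    "read_structure",
    "write_structure",
    "contact_count",
    "select_candidates",
    "excise_complex",
    "write_complex",
    "make_fixture_structure",
]

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# single-bond perception: covalent if pairwise distance < 1.3 * (r_a + r_b)
COVALENT_RADII = {"C": 0.77, "N": 0.70, "O": 0.66, "S": 1.04, "SE": 1.17, "P": 1.10}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple  # (x, y, z) in Angstrom


@dataclass(frozen=True)
class ResidueRef:
    chain: str
    index: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain}/{self.index}{self.icode}"


@dataclass
class Residue:
    ref: ResidueRef
    name: str
    atoms: list

    @property
    def heavy_atoms(self):
        return [a for a in self.atoms if a.element.upper() not in ("H", "D")]

    @property
    def sidechain_heavy_atoms(self):
        return [a for a in self.heavy_atoms if a.name not in BACKBONE_ATOMS]


@dataclass
class Structure:
    residues: list
    source_id: str = ""

    def __post_init__(self) -> None:
        for r in self.residues:
            for a in r.atoms:
                if not all(math.isfinite(v) for v in a.xyz):
                    raise ValueError(f"non-finite coordinate in {r.ref}")

    def find(self, ref: ResidueRef) -> Residue:
        for r in self.residues:
            if r.ref == ref:
                return r
        raise KeyError(f"residue {ref} not in structure")


@dataclass(frozen=True)
class VdmCandidate:
    ref: ResidueRef
    contact_count: int
    contacting_residues: tuple


@dataclass
class SyntheticComplex:
    receptor: Structure
    ligand_atoms: list
    ligand_name: str
    pocket_residues: tuple
    source_id: str = ""


# ---------------------------------------------------------------------------
# I/O


def read_structure(path) -> Structure:
    """Read a PDB file (first model); keep the highest-occupancy altloc."""
    st = gemmi.read_structure(str(path))
    model = st[0]
    residues = []
    for chain in model:
        for res in chain:
            best = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            atoms = [
                Atom(at.name, at.element.name, (at.pos.x, at.pos.y, at.pos.z))
                for at in best.values()
            ]
            ref = ResidueRef(chain.name, res.seqid.num, (res.seqid.icode or " ").strip())
            residues.append(Residue(ref, res.name, atoms))
    return Structure(residues, source_id=st.name or Path(path).stem)


def write_structure(structure: Structure, path) -> None:
    """Write the structure as a single-chain-per-id PDB file."""
    st = gemmi.Structure()
    st.name = structure.source_id or "CONF"
    model = gemmi.Model("1")
    chains = {}
    for r in structure.residues:
        if r.ref.chain not in chains:
            chains[r.ref.chain] = gemmi.Chain(r.ref.chain)
        res = gemmi.Residue()
        res.name = r.name
        res.seqid = gemmi.SeqId(r.ref.index, r.ref.icode or " ")
        for a in r.atoms:
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.pos = gemmi.Position(*a.xyz)
            at.occ = 1.0
            res.add_atom(at)
        chains[r.ref.chain].add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


# ---------------------------------------------------------------------------
# contact analysis


def _seq_distant(a: ResidueRef, b: ResidueRef, min_seq_sep: int) -> bool:
    if a.chain != b.chain:
        return True
    return abs(a.index - b.index) >= min_seq_sep


def contact_count(
    structure: Structure,
    ref: ResidueRef,
    dist_cutoff: float = 4.5,
    min_seq_sep: int = 7,
):
    """Count residues with a heavy atom within ``dist_cutoff`` of the
    candidate's sidechain heavy atoms, restricted to sequence-distant
    residues (|Δindex| >= min_seq_sep on the same chain; other chains always
    qualify).  Returns ``(count, list of contacting ResidueRef)``."""
    if dist_cutoff <= 0:
        raise ValueError("dist_cutoff must be positive")
    cand = structure.find(ref)
    sc = np.array([a.xyz for a in cand.sidechain_heavy_atoms])
    if sc.size == 0:
        return 0, []
    contacts = []
    for other in structure.residues:
        if other.ref == ref or not _seq_distant(ref, other.ref, min_seq_sep):
            continue
        xyz = np.array([a.xyz for a in other.heavy_atoms])
        if xyz.size == 0:
            continue
        dmin = np.sqrt(((sc[:, None, :] - xyz[None, :, :]) ** 2).sum(-1)).min()
        if dmin <= dist_cutoff:
            contacts.append(other.ref)
    return len(contacts), contacts


def select_candidates(
    structure: Structure,
    min_contacts: int = 4,
    dist_cutoff: float = 4.5,
    min_seq_sep: int = 7,
):
    """All standard residues with sidechain heavy atoms and enough
    sequence-distant contacts, best first (ties by chain then index)."""
    out = []
    for res in structure.residues:
        if res.name not in STANDARD_AA or not res.sidechain_heavy_atoms:
            continue
        n, refs = contact_count(structure, res.ref, dist_cutoff, min_seq_sep)
        if n >= min_contacts:
            out.append(VdmCandidate(res.ref, n, tuple(refs)))
    out.sort(key=lambda c: (-c.contact_count, c.ref.chain, c.ref.index, c.ref.icode))
    return out


def excise_complex(
    structure: Structure,
    candidate: VdmCandidate,
    window: int = 2,
    include_ca: bool = False,
) -> SyntheticComplex:
    """Cut the candidate sidechain out as the ligand.

    The receptor loses every residue within ``window`` sequence positions of
    the candidate on its chain (the chain break of the augmentation); the
    pocket is the candidate's contact set restricted to surviving residues.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    cand = structure.find(candidate.ref)
    ligand = list(cand.sidechain_heavy_atoms)
    if include_ca:
        ligand = [a for a in cand.heavy_atoms if a.name == "CA"] + ligand
    keep = [
        r for r in structure.residues
        if r.ref.chain != candidate.ref.chain
        or abs(r.ref.index - candidate.ref.index) > window
    ]
    receptor = Structure(keep, source_id=structure.source_id)
    kept_refs = {r.ref for r in keep}
    pocket = tuple(ref for ref in candidate.contacting_residues if ref in kept_refs)
    return SyntheticComplex(receptor, ligand, cand.name, pocket,
                            source_id=structure.source_id)


# ---------------------------------------------------------------------------
# output


def _ligand_mol(complex_: SyntheticComplex):
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    conf = Chem.Conformer(len(complex_.ligand_atoms))
    for i, a in enumerate(complex_.ligand_atoms):
        idx = mol.AddAtom(Chem.Atom(a.element.capitalize()))
        conf.SetAtomPosition(idx, Point3D(*a.xyz))
    xyz = np.array([a.xyz for a in complex_.ligand_atoms])
    radii = [COVALENT_RADII.get(a.element.upper(), 0.77) for a in complex_.ligand_atoms]
    for i in range(len(xyz)):
        for j in range(i + 1, len(xyz)):
            if np.linalg.norm(xyz[i] - xyz[j]) < 1.3 * (radii[i] + radii[j]):
                mol.AddBond(i, j, Chem.BondType.SINGLE)
    m = mol.GetMol()
    m.AddConformer(conf)
    m.SetProp("_Name", f"{complex_.source_id}_{complex_.ligand_name}")
    for atom in m.GetAtoms():
        atom.SetNoImplicit(True)
    Chem.SanitizeMol(m, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    return m


def write_complex(complex_: SyntheticComplex, out_dir):
    """Emit receptor.pdb, ligand.pdb, ligand.sdf and pocket.tsv; returns paths."""
    from rdkit import Chem

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    try:
        paths["receptor"] = out / "receptor.pdb"
        write_structure(complex_.receptor, paths["receptor"])

        paths["ligand_pdb"] = out / "ligand.pdb"
        with open(paths["ligand_pdb"], "w") as fh:
            for i, a in enumerate(complex_.ligand_atoms, start=1):
                x, y, z = a.xyz
                fh.write(
                    f"HETATM{i:5d} {a.name:<4s}{complex_.ligand_name:>3s} L   1    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {a.element.upper():>2s}\n"
                )
            fh.write("END\n")

        paths["ligand_sdf"] = out / "ligand.sdf"
        writer = Chem.SDWriter(str(paths["ligand_sdf"]))
        writer.write(_ligand_mol(complex_))
        writer.close()

        paths["pocket"] = out / "pocket.tsv"
        with open(paths["pocket"], "w") as fh:
            fh.write("chain\tresidue_index\ticode\n")
            for ref in complex_.pocket_residues:
                fh.write(f"{ref.chain}\t{ref.index}\t{ref.icode}\n")
    except OSError as err:
        raise OSError(f"failed writing synthetic complex under {out}: {err}") from err
    return paths


# ---------------------------------------------------------------------------
# programmatic fixtures (synthetic structures for tests and demos)


_SIDECHAIN_TEMPLATES = {
    "ALA": [("CB", "C", (0.0, 1.53, 0.0))],
    "SER": [("CB", "C", (0.0, 1.53, 0.0)), ("OG", "O", (0.0, 2.95, 0.0))],
    "LEU": [("CB", "C", (0.0, 1.53, 0.0)), ("CG", "C", (0.0, 2.95, 0.3)),
            ("CD1", "C", (1.25, 3.7, 0.3)), ("CD2", "C", (-1.25, 3.7, 0.3))],
    "TYR": [("CB", "C", (0.0, 1.53, 0.0)), ("CG", "C", (0.0, 2.95, 0.0)),
            ("CD1", "C", (1.2, 3.65, 0.0)), ("CD2", "C", (-1.2, 3.65, 0.0)),
            ("CE1", "C", (1.2, 5.05, 0.0)), ("CE2", "C", (-1.2, 5.05, 0.0)),
            ("CZ", "C", (0.0, 5.75, 0.0)), ("OH", "O", (0.0, 7.15, 0.0))],
    "GLY": [],
}

_BACKBONE_TEMPLATE = [
    ("N", "N", (-1.2, -0.8, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (1.3, -0.7, 0.0)),
    ("O", "O", (1.4, -1.9, 0.0)),
]


def _random_rotation(rng) -> np.ndarray:
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_fixture_structure(n_residues: int = 50, seed: int = 0,
                           names=None, chain: str = "A") -> Structure:
    """Generate a synthetic compact chain for testing.

    CA positions follow a self-avoiding-ish random walk confined to a sphere
    (so sequence-distant residues come into contact, as in folded proteins);
    each residue gets backbone plus a template sidechain under a random
    rotation.  Not physically valid geometry — a parseable stand-in for a
    crystal structure.
    """
    rng = np.random.default_rng(seed)
    if names is None:
        pool = ["ALA", "SER", "LEU", "TYR", "GLY"]
        names = [pool[rng.integers(len(pool))] for _ in range(n_residues)]
    radius = 2.4 * n_residues ** (1 / 3) + 4.0
    pos = np.zeros(3)
    residues = []
    for i in range(n_residues):
        for _ in range(200):
            step = rng.standard_normal(3)
            step *= 3.8 / np.linalg.norm(step)
            cand = pos + step
            if np.linalg.norm(cand) < radius:
                pos = cand
                break
        rot = _random_rotation(rng)
        atoms = []
        for name, elem, off in _BACKBONE_TEMPLATE + _SIDECHAIN_TEMPLATES[names[i]]:
            xyz = pos + rot @ np.asarray(off)
            atoms.append(Atom(name, elem, tuple(float(v) for v in xyz)))
        residues.append(Residue(ResidueRef(chain, i + 1), names[i], atoms))
    return Structure(residues, source_id=f"fixture-{seed}")
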