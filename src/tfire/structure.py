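"""Protein/DNA complex structures and operations on them.

The central container is :class:`ComplexStructure`: heavy atoms of one
protein/DNA complex partitioned by molecule class, with Watson-Crick base
pairs detected geometrically and the *effective binding site* defined as the
base pairs having at least one atom within 10 A of the protein.  On top of it
sit the two structural operations the prediction strategy needs:

* :func:`substitute_base_pair` - replace one pair by any of the four standard
  pairs on a bit-identical sugar-phosphate backbone (the "threading" move);
* :func:`perturb_dna` - a seeded rigid-body rotation + translation of the
  whole DNA, scaled to land in a prescribed RMSD interval, emulating the use
  of approximate (docked or modeled) complex geometry as template.

Hydrogens, waters, heteroatoms, alternate locations beyond 'A' and models
beyond the first are all discarded on reading.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from .bases import (
    BACKBONE_NAMES,
    BASE_ATOMS,
    BASE_FROM_RESNAME,
    COMPLEMENT,
    GLYCOSIDIC_N,
    PDB_RESNAME,
    SUGAR_C1,
    WC_NITROGEN,
    base_frame,
    base_ring_atoms,
    ideal_base_in_frame,
)

STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Default interface cutoff: a base pair belongs to the effective binding
#: site if any of its atoms lies within this distance of the protein.
INTERFACE_CUTOFF = 10.0

PAIR_TYPES = ("A-T", "C-G", "G-C", "T-A")

ResidueKey = tuple[str, int]


@dataclass
class Atom:
    """One heavy atom with its residue context."""

    name: str
    residue_name: str
    residue_index: int
    chain_id: str
    coords: np.ndarray
    molecule_class: str  # "protein" | "dna"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def element(self) -> str:
        for ch in self.name:
            if ch.isalpha():
                return ch.upper()
        raise ValueError(f"cannot infer element from atom name {self.name!r}")

    def copy(self) -> "Atom":
        return Atom(self.name, self.residue_name, self.residue_index,
                    self.chain_id, self.coords.copy(), self.molecule_class)


@dataclass(frozen=True)
class BasePair:
    """One Watson-Crick pair, indexed 1-based along the first DNA strand."""

    position: int
    strand1_residue: ResidueKey
    strand2_residue: ResidueKey
    pair_type: str

    def __post_init__(self) -> None:
        if self.pair_type not in PAIR_TYPES:
            raise ValueError(f"unknown pair type {self.pair_type!r}")


@dataclass(frozen=True)
class PerturbationSpec:
    """Rigid DNA perturbation request: target RMSD in (group_n - 1, group_n]."""

    group_n: int
    seed: int
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.group_n not in (1, 2, 3, 4):
            raise ValueError("group_n must be in 1..4")


@dataclass
class ComplexStructure:
    protein_atoms: list[Atom]
    dna_atoms: list[Atom]
    base_pairs: list[BasePair] = field(default_factory=list)
    tfbs_positions: tuple[int, ...] = ()
    source_id: str = ""

    @property
    def Ln(self) -> int:
        """Length of the effective binding site (Fig.-1 sense)."""
        return len(self.tfbs_positions)

    # -- indexed access helpers -------------------------------------------

    def protein_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.protein_atoms]).reshape(-1, 3)

    def dna_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.dna_atoms]).reshape(-1, 3)

    def dna_residues(self) -> dict[ResidueKey, list[Atom]]:
        res: dict[ResidueKey, list[Atom]] = {}
        for a in self.dna_atoms:
            res.setdefault((a.chain_id, a.residue_index), []).append(a)
        return res

    def pair_by_position(self, position: int) -> BasePair:
        for bp in self.base_pairs:
            if bp.position == position:
                return bp
        raise KeyError(f"no base pair at position {position}")

    def pair_atoms(self, position: int) -> list[Atom]:
        bp = self.pair_by_position(position)
        keys = {bp.strand1_residue, bp.strand2_residue}
        return [a for a in self.dna_atoms if (a.chain_id, a.residue_index) in keys]

    def pair_base_atoms(self, position: int) -> list[Atom]:
        """Base (non-backbone, non-sugar) atoms of both residues of a pair."""
        return [a for a in self.pair_atoms(position) if a.name not in BACKBONE_NAMES]

    def native_sequence(self) -> str:
        """First-strand bases of the effective binding site, 5'->3'."""
        out = []
        for pos in self.tfbs_positions:
            out.append(self.pair_by_position(pos).pair_type[0])
        return "".join(out)

    def copy(self) -> "ComplexStructure":
        return ComplexStructure(
            [a.copy() for a in self.protein_atoms],
            [a.copy() for a in self.dna_atoms],
            list(self.base_pairs),
            tuple(self.tfbs_positions),
            self.source_id,
        )


# ---------------------------------------------------------------------------
# reading / writing


def _normalize_atom_name(name: str) -> str:
    return name.strip().replace("*", "'")


def read_complex(pdb_source, protein_chains, dna_chains, *, source_id: str | None = None,
                 interface_cutoff: float = INTERFACE_CUTOFF) -> ComplexStructure:
    """Read a PDB-format complex and set up pairing and the binding site.

    ``pdb_source`` is a path or text stream; ``protein_chains``/``dna_chains``
    are chain-id iterables (a comma-separated string is accepted).  Waters,
    heteroatoms, hydrogens, altLocs other than ' '/'A' and models beyond the
    first are dropped.
    """
    if isinstance(protein_chains, str):
        protein_chains = [c for c in protein_chains.split(",") if c]
    if isinstance(dna_chains, str):
        dna_chains = [c for c in dna_chains.split(",") if c]
    protein_chains, dna_chains = list(protein_chains), list(dna_chains)
    if not dna_chains:
        raise ValueError("at least one DNA chain is required")

    if isinstance(pdb_source, (str,)) and "\n" not in pdb_source:
        handle = open(pdb_source)
    elif isinstance(pdb_source, str):
        handle = io.StringIO(pdb_source)
    else:
        handle = pdb_source
    parser = PDBParser(QUIET=True)
    model = next(parser.get_structure("complex", handle).get_models())

    present = {chain.id for chain in model}
    for cid in protein_chains + dna_chains:
        if cid not in present:
            raise ValueError(f"chain {cid!r} not present in structure")

    protein_atoms: list[Atom] = []
    dna_atoms: list[Atom] = []
    for chain in model:
        if chain.id in protein_chains:
            role = "protein"
        elif chain.id in dna_chains:
            role = "dna"
        else:
            continue
        for residue in chain:
            hetflag = residue.id[0]
            if hetflag != " ":
                continue  # waters / heteroatoms
            resname = residue.resname.strip()
            if role == "dna" and resname in STANDARD_AMINO_ACIDS:
                raise ValueError(f"DNA chain {chain.id!r} contains amino acid {resname}")
            if role == "protein" and resname not in STANDARD_AMINO_ACIDS:
                raise ValueError(f"protein chain {chain.id!r} contains non-amino-acid {resname}")
            if role == "dna" and resname not in BASE_FROM_RESNAME:
                raise ValueError(f"unsupported nucleotide {resname!r} in chain {chain.id!r}")
            for atom in residue:
                if atom.element in ("H", "D"):
                    continue
                if atom.get_altloc() not in (" ", "A"):
                    continue
                name = _normalize_atom_name(atom.get_name())
                if name.startswith("H") and not name.startswith("HO"):
                    # belt-and-braces for files without element columns
                    if atom.element in ("", " "):
                        continue
                target = protein_atoms if role == "protein" else dna_atoms
                target.append(Atom(name, resname, residue.id[1], chain.id,
                                   np.array(atom.coord, dtype=float), role))
    if not dna_atoms:
        raise ValueError("no DNA atoms found in the requested chains")

    structure = ComplexStructure(protein_atoms, dna_atoms, source_id=source_id or "complex")
    structure.base_pairs = detect_base_pairs(structure)
    structure.tfbs_positions = effective_tfbs(structure, cutoff=interface_cutoff)
    return structure


def write_complex(structure: ComplexStructure, stream=None) -> str:
    """Serialize to PDB ATOM records (fixed-width, 3-decimal coordinates)."""
    lines = []
    serial = 1
    for atom in list(structure.protein_atoms) + list(structure.dna_atoms):
        resname = atom.residue_name
        if atom.molecule_class == "dna":
            resname = PDB_RESNAME[BASE_FROM_RESNAME[resname]]
        name = atom.name
        # Standard alignment: 1-char elements start in column 14.
        field4 = name if len(name) == 4 else f" {name:<3s}"
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {serial:5d} {field4}{'':1s}{resname:>3s} {atom.chain_id:1s}"
            f"{atom.residue_index:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
        serial += 1
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


# ---------------------------------------------------------------------------
# base pairing and the effective binding site


def _residue_base(atoms: list[Atom]) -> str:
    return BASE_FROM_RESNAME[atoms[0].residue_name]


def _residue_atom(atoms: list[Atom], name: str) -> Atom:
    for a in atoms:
        if a.name == name:
            return a
    raise KeyError(f"residue {atoms[0].chain_id}:{atoms[0].residue_index} lacks atom {name}")


def detect_base_pairs(structure: ComplexStructure) -> list[BasePair]:
    """Identify Watson-Crick pairs by identity plus geometry.

    A pair requires complementary base identities, a C1'-C1' separation of
    10.4 +/- 1.5 A and a purine-N1 to pyrimidine-N3 distance below 3.5 A.
    Pairs are ordered 5'->3' along the first DNA chain; unpairable residues
    are excluded with a warning.
    """
    residues = structure.dna_residues()
    if not residues:
        raise ValueError("structure has no DNA residues")
    chains: list[str] = []
    for key in residues:
        if key[0] not in chains:
            chains.append(key[0])
    if len(chains) < 2:
        raise ValueError("base pairing requires two DNA strands")

    first_chain = chains[0]
    first = sorted((k for k in residues if k[0] == first_chain), key=lambda k: k[1])
    others = [k for k in residues if k[0] != first_chain]

    pairs: list[BasePair] = []
    used: set[ResidueKey] = set()
    skipped = 0
    for key in first:
        atoms = residues[key]
        base = _residue_base(atoms)
        comp = COMPLEMENT[base]
        try:
            c1 = _residue_atom(atoms, SUGAR_C1).coords
            wc_n = _residue_atom(atoms, WC_NITROGEN[base]).coords
        except KeyError:
            skipped += 1
            continue
        partner = None
        best = np.inf
        for okey in others:
            if okey in used:
                continue
            oatoms = residues[okey]
            if _residue_base(oatoms) != comp:
                continue
            try:
                oc1 = _residue_atom(oatoms, SUGAR_C1).coords
                own = _residue_atom(oatoms, WC_NITROGEN[comp]).coords
            except KeyError:
                continue
            d_c1 = float(np.linalg.norm(c1 - oc1))
            d_n = float(np.linalg.norm(wc_n - own))
            if abs(d_c1 - 10.4) <= 1.5 and d_n < 3.5 and d_n < best:
                partner, best = okey, d_n
        if partner is None:
            skipped += 1
            continue
        used.add(partner)
        pairs.append(BasePair(len(pairs) + 1, key, partner, f"{base}-{comp}"))

    if skipped:
        warnings.warn(f"{skipped} DNA residue(s) could not be paired", stacklevel=2)
    if len(pairs) < 2:
        raise ValueError("fewer than 2 base pairs detected")
    return pairs


def effective_tfbs(structure: ComplexStructure, cutoff: float = INTERFACE_CUTOFF) -> tuple[int, ...]:
    """Base-pair positions with >= 1 atom within ``cutoff`` of the protein."""
    if not structure.base_pairs:
        raise ValueError("base pairs must be detected first")
    prot = structure.protein_coords()
    if prot.size == 0:
        raise ValueError("no interface: structure has no protein atoms")
    tree = cKDTree(prot)
    positions = []
    for bp in structure.base_pairs:
        coords = np.array([a.coords for a in structure.pair_atoms(bp.position)])
        dmin = tree.query(coords, k=1)[0].min()
        if dmin <= cutoff:
            positions.append(bp.position)
    if not positions:
        raise ValueError("no interface: no base pair within cutoff of the protein")
    return tuple(positions)


# ---------------------------------------------------------------------------
# base-pair substitution


def _place_ideal_base(residue_atoms: list[Atom], new_base: str) -> list[Atom]:
    """Replace the base atoms of one nucleotide, keeping backbone bit-identical."""
    old_base = _residue_base(residue_atoms)
    c1 = _residue_atom(residue_atoms, SUGAR_C1).coords
    try:
        glyco = _residue_atom(residue_atoms, GLYCOSIDIC_N[old_base]).coords
        wc = _residue_atom(residue_atoms, WC_NITROGEN[old_base]).coords
    except KeyError as exc:
        raise ValueError(str(exc)) from exc
    ring = np.array([_residue_atom(residue_atoms, n).coords for n in base_ring_atoms(old_base)])
    origin_t, rot_t = base_frame(c1, glyco, wc, ring)

    ideal_atoms, origin_i, rot_i = ideal_base_in_frame(new_base)
    move = rot_t @ rot_i.T

    template = residue_atoms[0]
    out: list[Atom] = []
    for a in residue_atoms:
        if a.name in BACKBONE_NAMES:
            kept = a.copy()
            kept.residue_name = PDB_RESNAME[new_base]
            out.append(kept)
    for name in BASE_ATOMS[new_base]:
        coords = origin_t + move @ (ideal_atoms[name] - origin_i)
        out.append(Atom(name, PDB_RESNAME[new_base], template.residue_index,
                        template.chain_id, coords, "dna"))
    return out


def substitute_base_pair(structure: ComplexStructure, position: int, pair_type: str) -> ComplexStructure:
    """Replace the pair at ``position`` by ``pair_type`` on a fixed backbone.

    Both strands' base atoms are rebuilt from the idealized geometry placed
    via the local base frame of the residue being replaced; every atom outside
    the substituted pair, and all backbone/sugar atoms of the pair itself, are
    bit-identical to the input.  Returns a new structure.
    """
    if pair_type not in PAIR_TYPES:
        raise ValueError(f"unknown pair type {pair_type!r}")
    if position not in structure.tfbs_positions:
        raise ValueError(f"position {position} is not part of the effective binding site")
    bp = structure.pair_by_position(position)
    base1, base2 = pair_type.split("-")

    residues = structure.dna_residues()
    new_s1 = _place_ideal_base(residues[bp.strand1_residue], base1)
    new_s2 = _place_ideal_base(residues[bp.strand2_residue], base2)
    new_by_key = {bp.strand1_residue: new_s1, bp.strand2_residue: new_s2}

    dna_atoms: list[Atom] = []
    emitted: set[ResidueKey] = set()
    for a in structure.dna_atoms:
        key = (a.chain_id, a.residue_index)
        if key in new_by_key:
            if key not in emitted:
                dna_atoms.extend(new_by_key[key])
                emitted.add(key)
        else:
            dna_atoms.append(a.copy())

    new_pairs = [replace(p, pair_type=pair_type) if p.position == position else p
                 for p in structure.base_pairs]
    return ComplexStructure([a.copy() for a in structure.protein_atoms], dna_atoms,
                            new_pairs, tuple(structure.tfbs_positions), structure.source_id)


# ---------------------------------------------------------------------------
# rigid perturbation and RMSD


def compute_rmsd(coords_a, coords_b) -> float:
    """Plain coordinate RMSD over matched atoms (no re-superposition)."""
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate sets differ in shape: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def perturb_dna(structure: ComplexStructure, spec: PerturbationSpec) -> ComplexStructure:
    """Apply one seeded rigid rotation+translation to the DNA only.

    A single magnitude parameter scales both the rotation angle (about a
    random axis through the DNA centroid) and the translation along a random
    direction; it is bisected until the DNA RMSD versus the input lands in
    ``(group_n - 1, group_n]``.  The protein is untouched.
    """
    rng = np.random.default_rng(spec.seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)

    original = structure.dna_coords()
    center = original.mean(axis=0)
    lo_target = spec.group_n - 1.0
    hi_target = float(spec.group_n)

    def rmsd_at(m: float) -> float:
        rot = _rotation_matrix(axis, m * np.deg2rad(5.0))
        moved = (original - center) @ rot.T + center + direction * (m * 0.5)
        return compute_rmsd(original, moved)

    lo, hi = 0.0, 1.0
    attempts = 0
    while rmsd_at(hi) <= lo_target:
        hi *= 2.0
        attempts += 1
        if attempts > spec.max_attempts:
            raise RuntimeError("perturbation magnitude search exhausted max_attempts")
    m = hi
    while not (lo_target < rmsd_at(m) <= hi_target):
        attempts += 1
        if attempts > spec.max_attempts:
            raise RuntimeError("perturbation magnitude search exhausted max_attempts")
        if rmsd_at(m) > hi_target:
            hi = m
        else:
            lo = m
        m = 0.5 * (lo + hi)

    rot = _rotation_matrix(axis, m * np.deg2rad(5.0))
    shift = direction * (m * 0.5)
    out = structure.copy()
    for atom in out.dna_atoms:
        atom.coords = rot @ (atom.coords - center) + center + shift
    return out
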