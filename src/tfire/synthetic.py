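"""Synthetic fixtures: idealized duplexes, toy complexes, planted promoters.

Everything the prediction pipeline consumes can be generated here without
external downloads: idealized B-form DNA duplexes, small protein/DNA
complexes whose contact geometry prefers the native sequence by construction,
promoter sets with motif instances planted at annotated positions, and random
threading-decoy sequences.  All generators are pure functions of their
spec + seed.

The toy complex places one single-atom amino-acid probe per contacted base
pair in the major groove, ~3.5 A beyond an atom unique to the native base
(adenine N6, cytosine N4, guanine O6, thymine O4), and keys the probe's
residue type to the native base (ASN/GLN/ARG/THR for A/C/G/T).  Under
residue-specific atom typing, a potential trained on such a complex acquires
an unambiguous preference for the native base at each position - robust to
rigid perturbation of the DNA, since the preference lives in the atom types,
not in exact distances.  ``specificity_strength`` blends the probe position
between that base-anchored point (1.0) and a base-independent point in a
shared sugar frame (0.0, with a base-blind GLY CA probe), which removes the
sequence information from the training signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bases
from .bases import (
    PDB_RESNAME,
    SUGAR_C1,
    base_ring_atoms,
    helix_transform,
    residue_template,
)
from .pem import BASES, PWM, pwm_sample_sequence
from .scan import SiteAnnotation, merge_sites
from .structure import (
    Atom,
    ComplexStructure,
    detect_base_pairs,
    effective_tfbs,
)

#: Atom unique to each base, facing the major groove.
_SIGNATURE_ATOM = {"A": "N6", "C": "N4", "G": "O6", "T": "O4"}

#: Probe residue/atom pools keyed by native base (all standard amino-acid
#: types).  The pool is indexed by binding-site position so that every
#: (position, base) combination trains a distinct atom-type pair: contacts
#: learned at one position never generalize to another, as in a real
#: interface where each contact has its own geometry.
_PROBE_TYPES = {
    "A": [("ASN", n) for n in ("ND2", "OD1", "CG", "CB", "CA", "N", "C", "O")]
         + [("LEU", n) for n in ("CD1", "CD2", "CG", "CB", "CA", "N", "C", "O")],
    "C": [("GLN", n) for n in ("NE2", "OE1", "CD", "CG", "CB", "CA", "N", "C", "O")]
         + [("VAL", n) for n in ("CG1", "CG2", "CB", "CA", "N", "C", "O")],
    "G": [("ARG", n) for n in ("NH1", "NH2", "CZ", "NE", "CD", "CG", "CB", "CA", "N", "C", "O")]
         + [("SER", n) for n in ("OG", "CB", "CA", "N", "C")],
    "T": [("THR", n) for n in ("OG1", "CG2", "CB", "CA", "N", "C", "O")]
         + [("ILE", n) for n in ("CD1", "CG1", "CG2", "CB", "CA", "N", "C", "O")],
}

_GENERIC_PROBE = ("GLY", "CA")

#: Probe distance beyond the signature atom, A.  Kept off the distance-bin
#: grid so pair distances never sit exactly on a bin boundary.
_PROBE_DISTANCE = 3.47


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a sequence-specific toy complex."""

    sequence: str = "CTGCCGGTACCGGC"
    n_probe_atoms: int | None = None  # default: one probe per base pair
    specificity_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or any(b not in "ACGT" for b in seq):
            raise ValueError("sequence must be a nonempty A/C/G/T string")
        object.__setattr__(self, "sequence", seq)
        n = self.n_probe_atoms
        if n is not None and n < 4:
            raise ValueError("n_probe_atoms must be >= 4")
        if not 0.0 <= self.specificity_strength <= 1.0:
            raise ValueError("specificity_strength must lie in [0, 1]")


@dataclass(frozen=True)
class PromoterSpec:
    """Recipe for a planted-motif promoter set with annotations."""

    n_promoters: int = 10
    length: int = 500
    planted_sites: tuple[tuple[int, int], ...] | None = None  # (promoter, offset)
    background_gc: float = 0.38
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters < 1 or self.length < 1:
            raise ValueError("need at least one promoter of positive length")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError("background_gc must lie in [0, 1]")


# ---------------------------------------------------------------------------
# B-DNA


def make_bdna(sequence: str) -> ComplexStructure:
    """Idealized B-form duplex of ``sequence`` (chains D/E, protein-free).

    Helical rise 3.38 A and twist 36 degrees per step; the complementary
    strand is generated automatically.  Base pairs are detected with the
    ordinary geometric detector; the binding-site positions stay empty until
    a protein is present.
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("duplex needs at least 2 base pairs")
    if any(b not in "ACGT" for b in sequence):
        raise ValueError("sequence must contain only A/C/G/T")
    dna_atoms: list[Atom] = []
    n = len(sequence)
    for strand, chain in ((1, "D"), (2, "E")):
        for k in range(n):
            step = k if strand == 1 else n - 1 - k  # 5'->3' listing per strand
            base = sequence[step] if strand == 1 else bases.COMPLEMENT[sequence[step]]
            rot, trans = helix_transform(step)
            template = residue_template(base, second_strand=(strand == 2))
            for name, xyz in template.items():
                dna_atoms.append(Atom(name, PDB_RESNAME[base], k + 1, chain,
                                      rot @ xyz + trans, "dna"))
    structure = ComplexStructure([], dna_atoms, source_id=f"bdna_{sequence}")
    structure.base_pairs = detect_base_pairs(structure)
    return structure


# ---------------------------------------------------------------------------
# toy complexes


def _sugar_frame(atoms: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal frame built from sugar atoms only (identical for all bases)."""
    c1 = atoms[SUGAR_C1]
    x = atoms["O4'"] - c1
    x = x / np.linalg.norm(x)
    v = atoms["C2'"] - c1
    z = np.cross(x, v)
    z = z / np.linalg.norm(z)
    return c1, np.column_stack([x, np.cross(z, x), z])


#: Base-blind probe site expressed in sugar-frame coordinates.  The point
#: sits on the base-plane normal through C1': the local frames of the four
#: bases differ only by a small rotation about that axis, so every
#: probe-to-base-atom distance is exactly identical whichever base occupies
#: the position - the probe carries no sequence information at all.
def _generic_offset() -> np.ndarray:
    template = {n: np.asarray(v, dtype=float) for n, v in bases.BACKBONE_ATOMS.items()}
    origin, rot = _sugar_frame(template)
    above_c1 = template[SUGAR_C1] + np.array([0.0, 0.0, 4.2])
    return rot.T @ (above_c1 - origin)


_GENERIC_OFFSET = _generic_offset()


def _probe_position(structure: ComplexStructure, position: int, strength: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, str]:
    """Probe coordinates and native base for one base pair."""
    bp = structure.pair_by_position(position)
    base = bp.pair_type[0]
    residues = structure.dna_residues()
    atoms = {a.name: a.coords for a in residues[bp.strand1_residue]}
    ring = np.array([atoms[nm] for nm in base_ring_atoms(base)])
    centroid = ring.mean(axis=0)
    sig = atoms[_SIGNATURE_ATOM[base]]
    direction = sig - centroid
    direction /= np.linalg.norm(direction)
    specific = sig + _PROBE_DISTANCE * direction
    origin, rot = _sugar_frame(atoms)
    generic = origin + rot @ _GENERIC_OFFSET
    return strength * specific + (1.0 - strength) * generic, base


def make_toy_complex(spec: ToySpec) -> ComplexStructure:
    """Sequence-specific toy complex: idealized duplex plus typed probes.

    One probe pseudo-residue is placed per contacted base pair (all pairs by
    default, or ``n_probe_atoms`` evenly spaced ones).  The returned complex
    passes base-pair detection and has a nonempty effective binding site at
    the 10 A interface rule.
    """
    duplex = make_bdna(spec.sequence)
    rng = np.random.default_rng(spec.seed)
    n = len(spec.sequence)
    n_probes = n if spec.n_probe_atoms is None else min(spec.n_probe_atoms, n)
    contacted = np.linspace(1, n, n_probes).round().astype(int)
    protein_atoms: list[Atom] = []
    for res_idx, position in enumerate(dict.fromkeys(int(p) for p in contacted), start=1):
        coords, base = _probe_position(duplex, position, spec.specificity_strength, rng)
        if spec.specificity_strength > 0:
            pool = _PROBE_TYPES[base]
            resname, atom_name = pool[(position - 1) % len(pool)]
        else:
            resname, atom_name = _GENERIC_PROBE
        protein_atoms.append(Atom(atom_name, resname, res_idx, "P", coords, "protein"))
    structure = ComplexStructure(protein_atoms, duplex.dna_atoms, duplex.base_pairs,
                                 source_id=f"toy_{spec.sequence}")
    structure.tfbs_positions = effective_tfbs(structure)
    return structure


# ---------------------------------------------------------------------------
# promoters


def _random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[i] for i in rng.choice(4, size=length, p=p))


def make_promoters(spec: PromoterSpec, motif: PWM | str) -> tuple[str, list[SiteAnnotation]]:
    """Promoter FASTA with planted motif instances and their annotations.

    ``motif`` is either an exact sequence (planted verbatim) or a PWM (one
    instance drawn per site).  Default placement is one site per promoter at
    a seeded random offset; explicit ``planted_sites`` (promoter index,
    offset) pairs override it.  Background positions are i.i.d. with the
    given GC content, and any background window that equals the motif
    consensus exactly is resampled, so separability claims are constructive.
    Overlapping planted sites are merged in the returned annotations.
    """
    rng = np.random.default_rng(spec.seed)
    if isinstance(motif, str):
        consensus_seq = motif.upper()
        draw = lambda: consensus_seq
        motif_len = len(consensus_seq)
    else:
        from .pem import consensus as _consensus

        consensus_seq = _consensus(motif).sequence
        draw = lambda: pwm_sample_sequence(motif, rng)
        motif_len = motif.L
    if motif_len > spec.length:
        raise ValueError("motif longer than the promoter")

    if spec.planted_sites is None:
        planted = [(i, int(rng.integers(0, spec.length - motif_len + 1)))
                   for i in range(spec.n_promoters)]
    else:
        planted = [tuple(site) for site in spec.planted_sites]
        for i, offset in planted:
            if not 0 <= i < spec.n_promoters:
                raise ValueError(f"promoter index {i} out of range")
            if not 0 <= offset <= spec.length - motif_len:
                raise ValueError(f"planted site at {offset} does not fit")

    sequences = []
    for i in range(spec.n_promoters):
        seq = list(_random_sequence(spec.length, spec.background_gc, rng))
        sites_here = [off for j, off in planted if j == i]
        for off in sites_here:
            seq[off:off + motif_len] = draw()
        planted_pos = {p for off in sites_here for p in range(off, off + motif_len)}
        # Scrub accidental exact consensus matches away from the planted
        # offsets, resampling only background positions of each stray match.
        for _ in range(100):
            text = "".join(seq)
            hit = -1
            pos = text.find(consensus_seq)
            while pos != -1:
                if pos not in sites_here:
                    free = [p for p in range(pos, pos + motif_len)
                            if p not in planted_pos]
                    if free:
                        hit = pos
                        break
                pos = text.find(consensus_seq, pos + 1)
            if hit == -1:
                break
            fill = _random_sequence(len(free), spec.background_gc, rng)
            for p, b in zip(free, fill):
                seq[p] = b
        sequences.append("".join(seq))

    annotations = merge_sites([SiteAnnotation(f"orf{i + 1}", off, off + motif_len)
                               for i, off in planted])
    fasta = "".join(f">orf{i + 1}\n{s}\n" for i, s in enumerate(sequences))
    return fasta, annotations


def make_threading_decoys(sequence_length: int, n: int, seed: int) -> list[str]:
    """``n`` uniform random A/C/G/T sequences of the given length (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 4, size=(n, sequence_length))
    return ["".join(BASES[i] for i in row) for row in draws]
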