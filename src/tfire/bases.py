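"""Idealized nucleotide geometry.

Heavy-atom coordinates of the four standard bases in the standard base
reference frame (origin between the Watson-Crick edges, x toward the major
groove, base plane at z = 0), plus a consistent sugar-phosphate template used
when idealized B-form duplexes are generated from scratch.  The paired strand
of a Watson-Crick pair is obtained by the dyad flip ``(x, y, z) -> (x, -y, -z)``;
successive steps of a B-form helix apply a 36 degree twist about z and a
3.38 A rise.

These tables are the geometric vocabulary for base-pair substitution on a
fixed backbone: a base is placed into an existing residue by mapping the
table's local frame (C1', C1'->glycosidic-N direction, base-plane normal)
onto the frame measured from the residue being replaced.
"""

from __future__ import annotations

import numpy as np

# Heavy base atoms, standard reference frame, z = 0 plane.
BASE_ATOMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
}

# The raw tables are canonicalized so that all four bases share an exactly
# identical local frame: every base is translated to put its glycosidic
# nitrogen at the common anchor point and flattened onto the z = 0 plane.
# With a shared frame, placing an idealized base into an idealized residue is
# exact (base substitution reproduces native geometry bit-for-bit), which
# keeps substitution free of sub-0.1-A frame artifacts.
_GLYCO_ANCHOR = (-1.28725, 4.52275, 0.0)


def _canonicalize() -> None:
    glyco = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}
    for base, atoms in BASE_ATOMS.items():
        gx, gy, _ = atoms[glyco[base]]
        dx, dy = _GLYCO_ANCHOR[0] - gx, _GLYCO_ANCHOR[1] - gy
        for name, (x, y, _z) in list(atoms.items()):
            atoms[name] = (x + dx, y + dy, 0.0)


_canonicalize()

# Sugar-phosphate template shared by all residues, same frame as BASE_ATOMS.
# Bond lengths are stereochemically plausible (1.4-1.6 A); the template is an
# idealization, not a fiber-diffraction backbone.
BACKBONE_ATOMS: dict[str, tuple[float, float, float]] = {
    "P": (-2.350, 9.980, 0.750),
    "OP1": (-3.300, 11.130, 0.700),
    "OP2": (-1.050, 10.180, 0.030),
    "O5'": (-3.000, 8.650, 0.180),
    "C5'": (-4.200, 8.110, 0.750),
    "C4'": (-4.310, 6.630, 0.430),
    "O4'": (-3.514, 5.620, 0.990),
    "C3'": (-4.383, 6.299, -1.060),
    "O3'": (-5.527, 5.480, -1.340),
    "C2'": (-3.062, 5.583, -1.370),
    "C1'": (-2.477, 5.399, 0.000),
}

BACKBONE_NAMES = frozenset(BACKBONE_ATOMS)
SUGAR_C1 = "C1'"

# B-form helical parameters.
HELIX_RISE = 3.38  # A per step
HELIX_TWIST = 36.0  # degrees per step

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

# Glycosidic nitrogen: N9 for purines, N1 for pyrimidines.
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}

# Watson-Crick hydrogen-bond nitrogens used for pair detection:
# purine N1 pairs with pyrimidine N3.
WC_NITROGEN = {"A": "N1", "G": "N1", "C": "N3", "T": "N3"}

PDB_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
BASE_FROM_RESNAME = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T",
    "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T",
}


def base_ring_atoms(base: str) -> list[str]:
    """Ring atom names (exocyclic substituents excluded) of a base."""
    exocyclic = {"N6", "O6", "N2", "O2", "N4", "O4", "C7"}
    return [n for n in BASE_ATOMS[base] if n not in exocyclic]


def reverse_complement(sequence: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(sequence))


def helix_transform(step: int) -> tuple[np.ndarray, np.ndarray]:
    """Rotation matrix and translation placing a residue template at ``step``."""
    theta = np.deg2rad(HELIX_TWIST) * step
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    trans = np.array([0.0, 0.0, HELIX_RISE * step])
    return rot, trans


STRAND_FLIP = np.diag([1.0, -1.0, -1.0])


def residue_template(base: str, *, second_strand: bool = False) -> dict[str, np.ndarray]:
    """All heavy atoms of one nucleotide in the (possibly flipped) pair frame."""
    coords = {}
    for name, xyz in BACKBONE_ATOMS.items():
        coords[name] = np.asarray(xyz, dtype=float)
    for name, xyz in BASE_ATOMS[base].items():
        coords[name] = np.asarray(xyz, dtype=float)
    if second_strand:
        coords = {n: STRAND_FLIP @ v for n, v in coords.items()}
    return coords


def base_frame(c1: np.ndarray, glyco_n: np.ndarray, wc_n: np.ndarray,
               ring: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal local frame of a base from its anchoring geometry.

    Origin at C1'; x along C1'->glycosidic N; z the least-squares base-plane
    normal with its sign fixed by the in-plane handedness ``x cross
    (WC nitrogen - glycosidic N)``.  The Watson-Crick edge direction is far
    from parallel to x for every base, so the sign rule is well conditioned
    and identically-built frames agree between an idealized template and a
    measured residue.  Returns (origin, rotation with frame axes as columns).
    """
    x = glyco_n - c1
    x = x / np.linalg.norm(x)
    centroid = ring.mean(axis=0)
    centered = ring - centroid
    # Smallest principal direction of the ring = plane normal.
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    handed = np.cross(x, wc_n - glyco_n)
    if np.dot(normal, handed) < 0:
        normal = -normal
    z = normal - np.dot(normal, x) * x
    z = z / np.linalg.norm(z)
    y = np.cross(z, x)
    return c1, np.column_stack([x, y, z])


def ideal_base_in_frame(base: str) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Idealized base atoms plus the template's own local frame.

    The returned (origin, rotation) pair is what :func:`base_frame` yields for
    the unflipped template, so mapping template -> target is
    ``target_origin + R_target @ R_template.T @ (v - template_origin)``.
    """
    atoms = {n: np.asarray(v, dtype=float) for n, v in BASE_ATOMS[base].items()}
    c1 = np.asarray(BACKBONE_ATOMS[SUGAR_C1], dtype=float)
    glyco = atoms[GLYCOSIDIC_N[base]]
    wc = atoms[WC_NITROGEN[base]]
    ring = np.array([atoms[n] for n in base_ring_atoms(base)])
    origin, rot = base_frame(c1, glyco, wc, ring)
    return atoms, origin, rot
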