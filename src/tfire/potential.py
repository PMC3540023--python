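"""Distance-dependent knowledge-based protein/DNA potential.

The energy of a complex is a sum over cross protein/DNA heavy-atom pairs of a
tabulated term u(i, j, r), where i and j are *residue-specific* atom types
(e.g. (GUA, N2) is distinct from (ADE, N6)) and r is binned distance below a
cutoff.  The table is derived from observed pair counts against a
distance-scaled ideal-gas reference proportional to r**alpha:

    u(i, j, r) = -eta * ln[ N_obs~(i, j, r) / N_ref(i, j, r) ]

with N_obs~ the pseudo-count-augmented histogram and N_ref the r**alpha shape
normalized, per type pair, to the same total weight (so a histogram that
already follows the reference shape yields zero energy everywhere).

Four independent corrections can be toggled:

* ``use_reweight`` - every training structure contributes equal total weight,
  removing the bias toward large complexes;
* ``use_smoothing`` - finer 0.25 A bins smoothed with a [1,2,4,2,1]/10 kernel
  (mass-conserving, edge-truncated);
* ``use_dipolar`` - polar-polar pair counts weighted by the mutual alignment
  of the atoms' bond-derived dipole axes;
* ``use_volume_fraction`` - the reference is scaled by 2 * v_protein * v_dna,
  the heavy-atom volume fractions of the two unmixable molecule classes.

With all four enabled the function corresponds to the best-performing
"RaPvcFIRE" configuration; with only the volume fraction and pseudo-count it
is the plain "vcFIRE" baseline.  Training on the single template complex
being analyzed (tFIRE) is :func:`train_tfire`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
from scipy.spatial import cKDTree

from .bases import BASE_FROM_RESNAME
from .structure import Atom, ComplexStructure, STANDARD_AMINO_ACIDS

#: Canonical three-letter nucleotide codes used in atom types.
NUCLEOTIDE_CODE = {"A": "ADE", "C": "CYT", "G": "GUA", "T": "THY"}

#: Covalent-bond distance cutoff used to infer bonded neighbors.
BOND_CUTOFF = 1.8

POLAR_ELEMENTS = frozenset("NO")

#: Sentinel for "all base-pair positions" in interaction_energy.
ALL = None


class AtomType(NamedTuple):
    residue_name: str
    atom_name: str


def assign_atom_type(residue_name: str, atom_name: str) -> AtomType:
    """Residue-specific atom type; errors on nonstandard residues."""
    residue_name = residue_name.strip().upper()
    if residue_name in STANDARD_AMINO_ACIDS:
        return AtomType(residue_name, atom_name.strip())
    base = BASE_FROM_RESNAME.get(residue_name)
    if base is not None:
        return AtomType(NUCLEOTIDE_CODE[base], atom_name.strip())
    raise ValueError(f"nonstandard residue {residue_name!r} cannot be typed")


@dataclass(frozen=True)
class PotentialConfig:
    """Tunable parameters of the energy function.

    ``delta_r`` defaults to 0.25 A when smoothing is enabled and 0.5 A
    otherwise; ``r_cut / delta_r`` must be an integral number of bins.
    ``eta_rt`` sets the (arbitrary) energy unit; absolute scale is carried
    downstream by the Boltzmann beta and the threshold search, not here.
    """

    r_cut: float = 10.0
    delta_r: float | None = None
    alpha: float = 1.61
    eta_rt: float = 1.0
    pseudo_count: float = 0.5
    use_reweight: bool = True
    use_smoothing: bool = True
    use_dipolar: bool = True
    use_volume_fraction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_r is None:
            object.__setattr__(self, "delta_r", 0.25 if self.use_smoothing else 0.5)
        if self.r_cut <= 0 or self.delta_r <= 0:
            raise ValueError("r_cut and delta_r must be positive")
        nb = self.r_cut / self.delta_r
        if abs(nb - round(nb)) > 1e-9:
            raise ValueError("r_cut must be an integer multiple of delta_r")
        if self.use_smoothing and abs(self.delta_r - 0.25) > 1e-12:
            raise ValueError("smoothing requires delta_r = 0.25")

    @property
    def n_bins(self) -> int:
        return int(round(self.r_cut / self.delta_r))

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.r_cut, self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        edges = self.bin_edges
        return 0.5 * (edges[:-1] + edges[1:])

    def binning_matches(self, other: "PotentialConfig") -> bool:
        return (self.r_cut == other.r_cut and self.delta_r == other.delta_r
                and self.use_smoothing == other.use_smoothing
                and self.use_reweight == other.use_reweight
                and self.use_dipolar == other.use_dipolar)


PairKey = tuple[AtomType, AtomType]


@dataclass
class PairHistogram:
    """Weighted cross-pair distance counts per (protein type, DNA type)."""

    counts: dict[PairKey, np.ndarray]
    n_structures: int
    bin_edges: np.ndarray
    config: PotentialConfig

    def total_weight(self) -> float:
        return float(sum(c.sum() for c in self.counts.values()))


@dataclass
class Potential:
    energies: dict[PairKey, np.ndarray]
    config: PotentialConfig
    training_ids: list[str] = field(default_factory=list)

    def energy(self, type_protein: AtomType, type_dna: AtomType, r: float) -> float:
        """Tabulated u(i, j, r); zero at/beyond the cutoff or for unseen pairs."""
        if r >= self.config.r_cut:
            return 0.0
        table = self.energies.get((type_protein, type_dna))
        if table is None:
            return 0.0
        return float(table[int(r / self.config.delta_r)])


# ---------------------------------------------------------------------------
# pair accumulation


def _dipole_axes(atoms: list[Atom]) -> list[np.ndarray | None]:
    """Per-atom dipole axis: mean unit direction from bonded neighbors to atom."""
    if not atoms:
        return []
    coords = np.array([a.coords for a in atoms])
    tree = cKDTree(coords)
    pairs = tree.query_pairs(BOND_CUTOFF, output_type="ndarray")
    neighbors: list[list[int]] = [[] for _ in atoms]
    for i, j in pairs:
        neighbors[i].append(j)
        neighbors[j].append(i)
    axes: list[np.ndarray | None] = []
    for i, nbrs in enumerate(neighbors):
        if not nbrs:
            axes.append(None)
            continue
        vecs = coords[i] - coords[nbrs]
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        mean = vecs.mean(axis=0)
        norm = np.linalg.norm(mean)
        axes.append(mean / norm if norm > 1e-9 else None)
    return axes


def dipolar_weight(atom_i: Atom, neighbors_i: Iterable[np.ndarray],
                   atom_j: Atom, neighbors_j: Iterable[np.ndarray]) -> float:
    """Orientation weight in [0, 1] for one atom pair.

    Apolar atoms (C, S, P) always give 1.  For a polar-polar (N/O vs N/O)
    pair the weight is (1 + cos t_i)(1 + cos t_j)/4 where t_x is the angle
    between atom x's dipole axis (mean direction from its bonded heavy
    neighbors toward the atom) and the vector toward the partner atom.
    """
    if atom_i.element not in POLAR_ELEMENTS or atom_j.element not in POLAR_ELEMENTS:
        return 1.0
    axes = []
    for atom, nbrs in ((atom_i, list(neighbors_i)), (atom_j, list(neighbors_j))):
        if not nbrs:
            warnings.warn(f"atom {atom.name} has no bonded neighbor; dipolar weight 1",
                          stacklevel=2)
            return 1.0
        vecs = atom.coords - np.array(nbrs)
        vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
        mean = vecs.mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm < 1e-9:
            return 1.0
        axes.append(mean / norm)
    sep = atom_j.coords - atom_i.coords
    dist = np.linalg.norm(sep)
    if dist < 1e-9:
        return 1.0
    cos_i = float(np.dot(axes[0], sep / dist))
    cos_j = float(np.dot(axes[1], -sep / dist))
    w = (1.0 + cos_i) * (1.0 + cos_j) / 4.0
    return float(min(1.0, max(0.0, w)))


def _axis_weight(axis_i, axis_j, sep: np.ndarray, dist: float) -> float:
    if axis_i is None or axis_j is None or dist < 1e-9:
        return 1.0
    cos_i = float(np.dot(axis_i, sep) / dist)
    cos_j = float(np.dot(axis_j, -sep) / dist)
    return float(min(1.0, max(0.0, (1.0 + cos_i) * (1.0 + cos_j) / 4.0)))


def accumulate_pairs(structures: list[ComplexStructure], config: PotentialConfig) -> PairHistogram:
    """Histogram all cross protein/DNA atom pairs below the cutoff.

    With ``use_reweight`` every structure contributes the same total weight
    (scaled to the training set's mean pair count, so a single template is
    unaffected and duplicated structures change nothing after the
    per-structure normalization in :func:`build_potential`).  With
    ``use_dipolar`` each pair's unit weight is multiplied by its orientation
    factor before any reweighting.
    """
    if not structures:
        raise ValueError("at least one training structure is required")
    per_structure: list[dict[PairKey, np.ndarray]] = []
    totals: list[float] = []
    nb = config.n_bins
    for structure in structures:
        prot, dna = structure.protein_atoms, structure.dna_atoms
        hist: dict[PairKey, np.ndarray] = {}
        total = 0.0
        if prot and dna:
            pcoords = structure.protein_coords()
            dcoords = structure.dna_coords()
            ptypes = [assign_atom_type(a.residue_name, a.name) for a in prot]
            dtypes = [assign_atom_type(a.residue_name, a.name) for a in dna]
            if config.use_dipolar:
                paxes = _dipole_axes(prot)
                daxes = _dipole_axes(dna)
                if any(ax is None for ax in paxes + daxes):
                    warnings.warn("isolated atom(s) without bonded neighbors; "
                                  "dipolar weight 1 used", stacklevel=2)
            ptree = cKDTree(pcoords)
            dtree = cKDTree(dcoords)
            for i, js in enumerate(ptree.query_ball_tree(dtree, config.r_cut)):
                polar_i = prot[i].element in POLAR_ELEMENTS
                for j in js:
                    sep = dcoords[j] - pcoords[i]
                    dist = float(np.linalg.norm(sep))
                    if dist >= config.r_cut:
                        continue
                    w = 1.0
                    if config.use_dipolar and polar_i and dna[j].element in POLAR_ELEMENTS:
                        w = _axis_weight(paxes[i], daxes[j], sep, dist)
                    key = (ptypes[i], dtypes[j])
                    bins = hist.get(key)
                    if bins is None:
                        bins = hist[key] = np.zeros(nb)
                    bins[int(dist / config.delta_r)] += w
                    total += w
        per_structure.append(hist)
        totals.append(total)

    counts: dict[PairKey, np.ndarray] = {}
    positive = [t for t in totals if t > 0]
    mean_total = float(np.mean(positive)) if positive else 0.0
    for hist, total in zip(per_structure, totals):
        scale = (mean_total / total) if (config.use_reweight and total > 0) else 1.0
        for key, bins in hist.items():
            acc = counts.get(key)
            if acc is None:
                acc = counts[key] = np.zeros(nb)
            acc += bins * scale
    return PairHistogram(counts, len(structures), config.bin_edges, config)


def smooth(histogram: PairHistogram, config: PotentialConfig) -> PairHistogram:
    """Mass-conserving [1,2,4,2,1]/10 smoothing along distance (identity when off)."""
    if not config.use_smoothing:
        return histogram
    kernel = np.array([1.0, 2.0, 4.0, 2.0, 1.0]) / 10.0
    nb = len(histogram.bin_edges) - 1
    smoothed: dict[PairKey, np.ndarray] = {}
    for key, bins in histogram.counts.items():
        out = np.zeros(nb)
        for k in np.nonzero(bins)[0]:
            lo = max(0, k - 2)
            hi = min(nb, k + 3)
            piece = kernel[lo - (k - 2): 5 - ((k + 3) - hi)]
            out[lo:hi] += bins[k] * piece / piece.sum()
        smoothed[key] = out
    return PairHistogram(smoothed, histogram.n_structures, histogram.bin_edges,
                         histogram.config)


def volume_fraction_factor(structures: list[ComplexStructure]) -> tuple[float, float]:
    """Heavy-atom count fractions (v_protein, v_dna) over the training set."""
    if not structures:
        raise ValueError("at least one structure is required")
    n_prot = sum(len(s.protein_atoms) for s in structures)
    n_dna = sum(len(s.dna_atoms) for s in structures)
    total = n_prot + n_dna
    if total == 0:
        raise ValueError("training set contains no atoms")
    return n_prot / total, n_dna / total


def build_potential(histogram: PairHistogram, structures: list[ComplexStructure],
                    config: PotentialConfig) -> Potential:
    """Turn a pair histogram into an energy table against the r**alpha reference."""
    if not histogram.config.binning_matches(config):
        raise ValueError("histogram was built with a different configuration")
    shape = (config.bin_centers / config.r_cut) ** config.alpha
    f_vc = 1.0
    if config.use_volume_fraction:
        v_p, v_d = volume_fraction_factor(structures)
        if v_p == 0 or v_d == 0:
            raise ValueError("volume-fraction correction needs both molecule classes")
        f_vc = 2.0 * v_p * v_d
    energies: dict[PairKey, np.ndarray] = {}
    divisor = histogram.n_structures if config.use_reweight else 1
    for key, bins in histogram.counts.items():
        obs = bins / divisor + config.pseudo_count
        ref = shape * (obs.sum() / shape.sum()) * f_vc
        with np.errstate(divide="ignore"):
            u = -config.eta_rt * np.log(obs / ref)
        u[~np.isfinite(u)] = 0.0  # only reachable with pseudo_count = 0
        energies[key] = u
    return Potential(energies, config, [s.source_id for s in structures])


def train_tfire(template: ComplexStructure, config: PotentialConfig | None = None) -> Potential:
    """Train the potential on the single template complex being analyzed."""
    config = config or PotentialConfig()
    hist = accumulate_pairs([template], config)
    if hist.total_weight() == 0:
        raise ValueError("empty interface: no protein-DNA atom pair within r_cut")
    hist = smooth(hist, config)
    return build_potential(hist, [template], config)


# ---------------------------------------------------------------------------
# energy evaluation


def interaction_energy(potential: Potential, structure: ComplexStructure,
                       dna_subset=ALL) -> float:
    """Binding energy summed over protein x DNA-base atom pairs.

    ``dna_subset`` restricts the DNA side to the base atoms of the given
    base-pair positions (``ALL``/None means every detected pair).  Backbone
    and sugar atoms are excluded: the backbone is invariant under base-pair
    substitution, so its contribution is a per-position constant.
    """
    if dna_subset is ALL:
        positions = [bp.position for bp in structure.base_pairs]
    else:
        positions = sorted(dna_subset)
    dna_atoms = [a for p in positions for a in structure.pair_base_atoms(p)]
    if not dna_atoms or not structure.protein_atoms:
        return 0.0
    ptypes = [assign_atom_type(a.residue_name, a.name) for a in structure.protein_atoms]
    dtypes = [assign_atom_type(a.residue_name, a.name) for a in dna_atoms]
    pcoords = structure.protein_coords()
    dcoords = np.array([a.coords for a in dna_atoms])
    r_cut = potential.config.r_cut
    tree = cKDTree(dcoords)
    total = 0.0
    for i, js in enumerate(cKDTree(pcoords).query_ball_tree(tree, r_cut)):
        for j in js:
            dist = float(np.linalg.norm(dcoords[j] - pcoords[i]))
            if dist < r_cut:
                total += potential.energy(ptypes[i], dtypes[j], dist)
    return total


# ---------------------------------------------------------------------------
# serialization


def write_potential(potential: Potential, stream=None) -> str:
    """Tab-separated table with a ``# key=value`` config header."""
    cfg = potential.config
    lines = [f"# r_cut={cfg.r_cut}", f"# delta_r={cfg.delta_r}", f"# alpha={cfg.alpha}",
             f"# eta_rt={cfg.eta_rt}", f"# pseudo_count={cfg.pseudo_count}",
             f"# use_reweight={cfg.use_reweight}", f"# use_smoothing={cfg.use_smoothing}",
             f"# use_dipolar={cfg.use_dipolar}",
             f"# use_volume_fraction={cfg.use_volume_fraction}",
             f"# training_ids={','.join(potential.training_ids)}",
             "res_i\tatom_i\tres_j\tatom_j\tbin_low\tbin_high\tenergy"]
    edges = cfg.bin_edges
    for (ti, tj), table in sorted(potential.energies.items()):
        for k, u in enumerate(table):
            if u != 0.0:
                lines.append(f"{ti.residue_name}\t{ti.atom_name}\t{tj.residue_name}"
                             f"\t{tj.atom_name}\t{edges[k]:.3f}\t{edges[k + 1]:.3f}\t{u:.6f}")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


def read_potential(source) -> Potential:
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    meta: dict[str, str] = {}
    rows = []
    for line in text.splitlines():
        if line.startswith("#"):
            k, _, v = line[1:].strip().partition("=")
            meta[k] = v
        elif line and not line.startswith("res_i"):
            rows.append(line.split("\t"))
    as_bool = lambda s: s == "True"
    config = PotentialConfig(
        r_cut=float(meta["r_cut"]), delta_r=float(meta["delta_r"]),
        alpha=float(meta["alpha"]), eta_rt=float(meta["eta_rt"]),
        pseudo_count=float(meta["pseudo_count"]),
        use_reweight=as_bool(meta["use_reweight"]),
        use_smoothing=as_bool(meta["use_smoothing"]),
        use_dipolar=as_bool(meta["use_dipolar"]),
        use_volume_fraction=as_bool(meta["use_volume_fraction"]))
    energies: dict[PairKey, np.ndarray] = {}
    for res_i, atom_i, res_j, atom_j, bin_low, _, energy in rows:
        key = (AtomType(res_i, atom_i), AtomType(res_j, atom_j))
        table = energies.setdefault(key, np.zeros(config.n_bins))
        table[int(float(bin_low) / config.delta_r + 0.5)] = float(energy)
    ids = [t for t in meta.get("training_ids", "").split(",") if t]
    return Potential(energies, config, ids)
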