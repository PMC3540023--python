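"""Position energy matrices, position weight matrices and their comparison.

A PEM holds, for each effective binding-site position, the binding energy of
the template complex with that position substituted by each of the four
Watson-Crick pairs (A-T, C-G, G-C, T-A, keyed by the first-strand base
A, C, G, T).  The Boltzmann conversion p(i, j) proportional to
exp(-beta * e(i, j)), normalized within each position, turns a PEM into a
PWM; beta defaults to 0.05 per arbitrary energy unit.  PWMs are compared with
the psi dissimilarity, implemented as the mean per-position total-variation
distance (0 for identical matrices, at most 1, symmetric, metric).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .structure import ComplexStructure, PAIR_TYPES, substitute_base_pair
from .potential import Potential, interaction_energy

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

DEFAULT_BETA = 0.05


@dataclass
class PEM:
    """L x 4 substitution-energy matrix (columns A-T, C-G, G-C, T-A)."""

    energies: np.ndarray
    tf_id: str = ""
    positions: tuple[int, ...] = ()
    native: tuple[int, ...] = ()  # column index of the template's own pair, if known

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.ndim != 2 or self.energies.shape[1] != 4:
            raise ValueError("PEM must be an L x 4 matrix")
        if not np.all(np.isfinite(self.energies)):
            raise ValueError("PEM entries must be finite")

    @property
    def L(self) -> int:
        return self.energies.shape[0]


@dataclass
class PWM:
    """L x 4 base-probability matrix in alphabet order A, C, G, T."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be an L x 4 matrix")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("PWM entries must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")

    @property
    def L(self) -> int:
        return self.probs.shape[0]


@dataclass
class PsiScore:
    value: float
    per_position: list[float] = field(default_factory=list)


class Consensus(NamedTuple):
    sequence: str
    ties: tuple[bool, ...]


# ---------------------------------------------------------------------------
# construction


def build_pem(potential: Potential, structure: ComplexStructure, tf_id: str = "") -> PEM:
    """Substitute every binding-site position by all four pairs and score each.

    Entry (p, i) is the interaction energy between the protein and the base
    atoms of the substituted pair alone, so entries are comparable across
    positions (the invariant backbone cancels).  The input structure is not
    modified.
    """
    positions = tuple(structure.tfbs_positions)
    energies = np.zeros((len(positions), 4))
    native = []
    for row, pos in enumerate(positions):
        native.append(PAIR_TYPES.index(structure.pair_by_position(pos).pair_type))
        for col, pair_type in enumerate(PAIR_TYPES):
            substituted = substitute_base_pair(structure, pos, pair_type)
            energies[row, col] = interaction_energy(potential, substituted, {pos})
    return PEM(energies, tf_id or structure.source_id, positions, tuple(native))


def pem_to_pwm(pem: PEM, beta: float = DEFAULT_BETA) -> PWM:
    """Boltzmann conversion with per-position normalization (max-subtracted)."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    logits = -beta * pem.energies
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return PWM(w / w.sum(axis=1, keepdims=True))


def even_pwm(L: int) -> PWM:
    """The uniform reference PWM: probability 0.25 everywhere."""
    if L < 1:
        raise ValueError("L must be >= 1")
    return PWM(np.full((L, 4), 0.25))


def zero_reference(pem: PEM) -> PEM:
    """Keep only each position's lowest energy; zero the other entries (ties kept)."""
    energies = np.zeros_like(pem.energies)
    mins = pem.energies.min(axis=1, keepdims=True)
    keep = pem.energies == mins
    energies[keep] = pem.energies[keep]
    return PEM(energies, pem.tf_id, pem.positions, pem.native)


def mutate_template_sequence(structure: ComplexStructure, seed: int) -> ComplexStructure:
    """Randomize the template's binding-site sequence, position by position.

    Every effective binding-site position is substituted by a pair drawn
    uniformly from the four types (seeded); the backbone is untouched.  This
    is the mutant-template control that destroys the sequence information in
    the template while keeping its geometry.
    """
    rng = np.random.default_rng(seed)
    out = structure
    for pos in structure.tfbs_positions:
        out = substitute_base_pair(out, pos, PAIR_TYPES[rng.integers(4)])
    return out


# ---------------------------------------------------------------------------
# comparison


def psi_test(pwm_a: PWM, pwm_b: PWM) -> PsiScore:
    """Mean per-position total-variation distance between two aligned PWMs."""
    if pwm_a.L != pwm_b.L:
        raise ValueError(f"PWM lengths differ: {pwm_a.L} vs {pwm_b.L}")
    per_position = 0.5 * np.abs(pwm_a.probs - pwm_b.probs).sum(axis=1)
    return PsiScore(float(per_position.mean()), [float(x) for x in per_position])


def consensus(pwm: PWM) -> Consensus:
    """Per-position argmax base; ties broken alphabetically and flagged."""
    idx = pwm.probs.argmax(axis=1)
    maxima = pwm.probs.max(axis=1, keepdims=True)
    ties = (np.isclose(pwm.probs, maxima, atol=1e-12).sum(axis=1) > 1)
    return Consensus("".join(BASES[i] for i in idx), tuple(bool(t) for t in ties))


# ---------------------------------------------------------------------------
# I/O: matrix TSV (rows A, C, G, T; columns 1..L) and JASPAR text


def write_matrix(matrix: np.ndarray, stream=None) -> str:
    rows = ["\t".join([BASES[i]] + [f"{v:.6g}" for v in matrix[:, i]]) for i in range(4)]
    text = "\n".join(rows) + "\n"
    if stream is not None:
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


def read_matrix(source) -> np.ndarray:
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    values = {}
    for line in text.strip().splitlines():
        parts = line.split("\t")
        values[parts[0]] = [float(v) for v in parts[1:]]
    return np.array([values[b] for b in BASES]).T


def write_jaspar(pwm: PWM, motif_id: str, stream=None) -> str:
    """JASPAR bracket dialect: '>ID' then one 'A [ ... ]' line per base."""
    lines = [f">{motif_id}"]
    for i, base in enumerate(BASES):
        cells = " ".join(f"{v:9.6f}" for v in pwm.probs[:, i])
        lines.append(f"{base} [ {cells} ]")
    text = "\n".join(lines) + "\n"
    if stream is not None:
        if isinstance(stream, str):
            with open(stream, "w") as fh:
                fh.write(text)
        else:
            stream.write(text)
    return text


def read_jaspar(source) -> dict[str, PWM]:
    """Read JASPAR text (bracket or plain 4-line dialect); values are normalized."""
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    from Bio import motifs as bio_motifs

    out: dict[str, PWM] = {}
    for motif in bio_motifs.parse(io.StringIO(text), "jaspar"):
        counts = np.array([list(motif.counts[b]) for b in BASES]).T
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals <= 0):
            raise ValueError(f"motif {motif.matrix_id or motif.name} has empty positions")
        name = motif.matrix_id or motif.name or f"motif{len(out) + 1}"
        out[name] = PWM(counts / totals)
    if not out:
        raise ValueError("no motifs found in JASPAR input")
    return out


def pwm_sample_sequence(pwm: PWM, rng: np.random.Generator) -> str:
    """Draw one sequence from a PWM (used when planting motif instances)."""
    return "".join(BASES[rng.choice(4, p=pwm.probs[j])] for j in range(pwm.L))
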