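# Methods

## The energy function

The potential is an all-heavy-atom, distance-dependent knowledge-based
energy for protein/DNA binding. Rigid-body binding is assumed: intra-protein
and intra-DNA terms are constant on binding and are never counted — only
cross protein/DNA atom pairs enter. Atom types are residue-specific
(`(residue, atom name)` exactly), so `(GUA, N2)` and `(ADE, N6)` are
distinct types; this is what lets a potential encode sequence preference at
all.

For each type pair `(i, j)` the observed distances below `r_cut` are
histogrammed in bins of `Δr`, and the energy per bin is

    ū(i, j, r) = −η · ln[ Ñ_obs(i, j, r) / N_ref(i, j, r) ]

* `Ñ_obs` — counts plus a pseudo-count per bin (default 0.5), which keeps
  every energy finite at low counts.
* `N_ref` — the distance-scaled ideal-gas shape `(r/r_cut)^α`, α = 1.61
  (the published exponent for this family of reference states),
  self-normalized per `(i, j)` so that a histogram already proportional to
  the reference yields zero energy in every bin. If the volume-fraction
  correction is on, the normalized reference is then multiplied by
  `2·v_protein·v_dna` (heavy-atom count fractions of the training set);
  applying the factor after normalization is deliberate — inside the
  normalization it would cancel identically.
* Type pairs never observed in training have no table entry and score 0
  (neutral). Extrapolating them from a pure-pseudo-count histogram would
  assign spuriously favorable energies at short range, because
  self-normalizing a flat histogram against the `r^α` shape makes the
  smallest-`r` bins look enriched.
* `ū = 0` at and beyond `r_cut` (default 10 Å, matching the interface
  definition below). Bins are half-open `[kΔr, (k+1)Δr)`.

Energies are in arbitrary units with `η = 1`; the absolute scale is
irrelevant downstream because the Boltzmann β and the threshold search carry
the scale.

### Corrections

Each correction is an independent toggle; all four are on by default (the
best-performing combination), and turning all off but the pseudo-count and
volume fraction gives the baseline variant.

* **Reweighting (`use_reweight`)** — pair-count statistics are biased toward
  large complexes. Each training structure's pair weights are scaled by
  `mean(total pair count) / (its total pair count)`, so every structure
  contributes equal total weight while the histogram keeps the raw-count
  scale (important: a fixed per-bin pseudo-count would otherwise swamp
  counts normalized to total weight 1). The table is finally divided by the
  number of structures, which makes training exactly invariant under
  duplicating any structure, and makes single-template training independent
  of the toggle.
* **Smoothing (`use_smoothing`)** — bins shrink to 0.25 Å and each `(i, j)`
  histogram is convolved with the fixed kernel `[1,2,4,2,1]/10`,
  edge-truncated and renormalized per source bin so total weight is
  conserved exactly.
* **Dipolar weight (`use_dipolar`)** — counts of polar-polar pairs (N/O vs
  N/O) are multiplied by `(1+cos θ_i)(1+cos θ_j)/4`, where `θ_x` is the
  angle between atom `x`'s dipole axis and the interatomic vector. The
  dipole axis is the mean unit direction from the atom's covalently bonded
  heavy neighbors (bond inferred at < 1.8 Å) to the atom. Atoms with no
  bonded neighbor fall back to weight 1 with a warning. Apolar atoms
  (C, S, P) are unweighted.
* **Volume fraction (`use_volume_fraction`)** — see `N_ref` above; it
  accounts for protein and DNA atoms being unmixable phases, so the random
  reference overestimates cross-pair availability.

### Template training (tFIRE)

`train_tfire` composes accumulate → smooth → build on the single complex
being analyzed. A general-purpose potential trained on many complexes is
sensitive to the exact protein/DNA placement of the template; a potential
trained on the template itself is, by construction, consistent with whatever
placement the template has, which is why prediction accuracy survives
rigid-body errors of several Å (see the perturbation results).

## Structures

Reading uses Bio.PDB: first model only, altLoc ' '/'A' only, no waters,
heteroatoms or hydrogens (crystal structures rarely resolve hydrogens, and
the potential family is heavy-atom). Nucleotides may be named DA/DC/DG/DT or
A/C/G/T. Watson-Crick pairs are detected by complementary identity plus
geometry (C1'-C1' within 10.4 ± 1.5 Å, purine-N1 to pyrimidine-N3 below
3.5 Å), ordered 5'→3' along the first DNA chain. The *effective binding
site* keeps the pairs with at least one atom within 10 Å of any protein
atom; its length is `Ln`.

### Base-pair substitution

A pair is replaced on a bit-identical backbone: the sugar-phosphate atoms
(P, OP1, OP2, O5', C5', C4', O4', C3', O3', C2', C1') are untouched, and
the base atoms of both strands are rebuilt from idealized heavy-atom base
geometries placed via a local frame — origin at C1', x toward the
glycosidic nitrogen, z the least-squares base-plane normal. The normal's
sign is fixed by the in-plane handedness of the Watson-Crick-edge vector
(glycosidic N → WC nitrogen) against x; the more obvious reference (ring
centroid) is nearly parallel to x for pyrimidines and misplaces bases by a
180° flip when substituting across purine/pyrimidine.

The idealized tables are standard-reference-frame base coordinates,
canonicalized so all four bases share an identical local frame (common
glycosidic-N anchor, exactly planar). On idealized structures substitution
is then exact to machine precision; on real structures self-substitution
reproduces the native base to well under the 0.8 Å idealization tolerance.

### Rigid perturbation

`perturb_dna` applies one seeded rigid rotation (random axis through the
DNA centroid) plus translation (random direction), with a single magnitude
parameter bisected until the DNA-vs-input RMSD lands in the requested
half-open interval `(n−1, n]` Å, n = 1..4. RMSD is computed without
re-superposition — the perturbation *is* the displacement being measured.

## PEM, PWM, ψ

The PEM entry for (position, pair) is the interaction energy restricted to
the substituted pair's base atoms. The backbone is identical across the
four substitutions, so its contribution is a per-position constant that
would cancel in the Boltzmann conversion anyway; excluding it keeps entries
comparable across positions. Consequently window threading is additive:
a sequence's energy is the sum of its per-position PEM entries.

`pem_to_pwm` is a per-position softmax of `−β·e` with max-subtraction;
β = 0.05 per arbitrary energy unit. The ψ dissimilarity between two aligned
PWMs is the mean per-position total-variation distance
`(1/L)·Σ_j ½·Σ_i |a_ij − b_ij|` — zero iff identical, bounded by 1,
symmetric, and a true metric, which is everything the comparisons rely on;
it is isolated in one function so an alternative definition can be swapped
in. Compared PWMs must be pre-aligned and equal-length; alignment search is
out of scope.

## Scanning and evaluation

Coordinates are 0-based half-open internally and 1-based inclusive in
file I/O for curated site tables. Overlapping or bookended annotated sites
are merged before evaluation. Windows containing N count toward the
`len − L + 1` total but score +∞ and are never predicted. Per promoter the
200 lowest-energy windows are retained; candidate cutoffs are the distinct
retained energies; "below the cutoff" is `≤`, so the maximizing candidate is
attainable, and ties go to the more stringent cutoff.

A site of length `Ld` is recovered (TP) if a predicted window overlaps it by
`Lo` with `Lo/Ld > 0.5` strictly, or — when the annotated site is longer
than the template site (`Ld > Ln`) — with `Lo/Ln > 0.5`. Predicted windows
matching no site are FPs; several windows on one site are one TP and no FP;
one window may recover two adjacent merged sites (counted as two TPs).
SE = TP/(TP+FN) over sites, SP = TP/(TP+FP). For ROC/AUC, negatives are
the retained candidate windows that match no site — the only negative set
that makes a false-positive rate computable in this design — and lower
energy means called-positive earlier; AUC equals the normalized
Mann-Whitney statistic. Scanning is forward-strand by default; the reverse
complement can be scanned on request. Summary tables report per-TF rows
plus Average and sample-SD (n−1) rows, computed at full precision and
rounded half-up to 2 decimals.

## Synthetic data: what it emulates, what it does not

`make_bdna` builds an idealized B-form duplex (rise 3.38 Å, twist 36°)
with a plausible but schematic sugar-phosphate template. `make_toy_complex`
adds one single-atom amino-acid probe per base pair, placed ≈3.5 Å beyond
an atom unique to the native base (A:N6, C:N4, G:O6, T:O4; the exact
distance 3.47 Å keeps pair distances off the bin grid). Probe types are
drawn from a per-base pool of standard amino-acid atom types indexed by
position, so every (position, base) contact trains a distinct atom-type
pair: contacts learned at one position never generalize to another, as in a
real interface where each contact has its own geometry. This construction
guarantees, rather than merely encourages, that a template-trained
potential prefers the native base at each position — and because the
preference lives in atom types, it survives rigid DNA perturbation.

At `specificity_strength = 0` the probe becomes a single base-blind type
placed on the base-plane normal through C1', a point whose distances to the
base atoms are identical whichever base occupies the position. The
potential can then learn only sequence composition; per-position
preferences collapse to one global winner (in expectation the most frequent
base), so recovery falls from ~1 to roughly the sequence's maximum base
frequency (~0.4 for random 12-mers) — near chance, and position-free,
but not exactly 0.25: with a self-trained potential no base-blind probe can
make the per-position argmin uniform.

`make_promoters` emits i.i.d.-background promoters (default 10 × 500 bp,
GC 0.38, roughly the yeast genomic value) with one motif instance planted
per promoter at a seeded offset (explicit placements and PWM-sampled
instances are supported); background windows exactly matching the motif
consensus are resampled so separability claims are constructive. What the
synthetic data does *not* emulate: real side-chain chemistry and packing,
water-mediated contacts, DNA deformation, degenerate/low-information
motifs, and background sequence composition structure — so passing the
synthetic suite demonstrates the machinery's correctness and the
template-training property, not expected accuracy on genomic data.

## Benchmark sizes and numerical choices

The bundled evaluation runs at: 14-bp template (the worked-example length),
10 promoters × 500 bp with one planted site each, 500 threading decoys, 20
mutant-template seeds, perturbation groups 1-4. The mutant control's
SE+SP averages ~1.0 (chance, given the threshold optimization) versus 2.0
for the native template, and perturbed templates retrain to full accuracy —
the orderings the method is designed to show.

Degenerate inputs are errors, not silent results: empty training
interfaces, single-class ROC labels, constant paired differences, zero
decoy variance, thresholding without sites. Argmax/argmin ties break
alphabetically (consensus, flagged) or toward the more stringent value
(threshold). All generators and stochastic tests are seeded; no global
random state is used anywhere.

## Known limitations

Only standard bases and the 20 standard amino acids are typed; modified
residues are rejected. NMR ensembles use model 1 only. The scanner assumes
annotations already live in promoter coordinates. The dipolar, smoothing
and reweighting forms are this package's concrete instantiations of their
stated motivations; they are deliberately isolated behind configuration
toggles so alternative forms can be substituted and compared.
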