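# Methods

## Scope and model

`ifacemap` implements the desk-scale analysis layer of a protein–protein
interface-mapping study: triage and clustering of rigid-body docking poses,
residue-level contact and energy statistics over trajectory-like frame
series, HSQC intensity screening, and binding-assay quantification. It does
not sample docking poses, integrate equations of motion, or process spectra;
those upstream computations are represented by synthetic generators with
planted ground truth, so every downstream contract can be verified exactly.

Coordinates are handled in ångström internally. RMSD values that feed the
clustering layer are reported in nanometres (`*_nm` fields), matching the
convention of trajectory-analysis tooling; contact cutoffs stay in Å.
Author residue numbering is preserved verbatim everywhere: FGF2 positions
use 18-kDa-isoform numbering (K54, K60, K127/R128/K133), α1 positions use
the human α1 frame (T382–V599, D560), with the pig crystal-structure frame
offset by two (T380–V597).

## Pose triage

The cascade applies, in order:

1. **Score retention** — keep the best ⌈n·f⌉ poses by interface score
   (lower = more favorable by default; the sign convention is
   configurable). The default f = 0.06 mirrors a production-scale run in
   which about 94% of generated poses are discarded on score; synthetic
   100-pose ensembles with 20 planted binders are instead run with f = 0.2
   so the retained count matches the planted prevalence. Boundary ties keep
   the lower pose id.
2. **Epitope contact** — a pose survives when any atom of the designated
   epitope residues lies strictly within the contact cutoff (default 6.0 Å)
   of any receptor atom. Equality at the cutoff discards: the rule is "less
   than", and the boundary convention is fixed so it is testable.
3. **Clash filter** — each pose is superposed onto a reference frame via a
   Kabsch fit on its receptor atoms and discarded if any ligand heavy atom
   falls within 2.0 Å of the supplied reference context (e.g. the rest of a
   full-length structure surrounding the fitted domain). The context
   deliberately excludes the fitted receptor domain itself by default —
   the ligand must contact that domain by design, so only overlap with the
   surroundings is a physical clash — but callers can pass any context set,
   including the receptor.
4. **GROMOS clustering** — pairwise ligand RMSD (Cα by default, heavy-atom
   optional) after superposing every model's receptor onto the first pose;
   iteratively the pose with the most neighbors within 0.6 nm becomes a
   cluster center and is removed together with its neighbors.
   Neighbor-count ties break to the lower pose id, and final labels are
   ordered by decreasing size. Each cluster reports its center
   (max-neighbor pose), its centroid/representative (smallest mean RMSD to
   the other members, ties to the lower pose id), its size, and its mean
   pairwise RMSD in nm.

Rigid-body perturbation (`perturb_pose`) draws a rotation about a uniform
random axis through the ligand centroid with angle uniform in
[0, max_rotation] and a translation uniform in the ball of radius
max_translation (defaults 8° and 3 Å). An `exact_magnitude` mode uses the
maxima as exact displacement magnitudes, for protocols that read "perturb
by 3 Å and 8°" literally.

## Interface statistics

A residue pair is in contact in a frame when any heavy-atom pair sits
strictly within the cutoff; the default 6.0 Å reuses the one distance rule
fixed elsewhere in the pipeline, and a tighter 4.5 Å convention is a
parameter away. Contact probability is the mean of that indicator over the
analysis window, which defaults to the last half of the frames (analysis of
equilibrated tails of paired 100-of-200-ns trajectories is the emulated
protocol). Persistent contacts require probability strictly above 0.5.
Per-residue contribution is the row/column sum of the map, so summed over
either side it equals the total of all entries — an identity tests enforce
to 1e-12.

Pairwise interaction energies are a deliberately transparent approximation:
truncated Coulomb f·q_iq_j/r with f = 138.935 kJ·mol⁻¹·nm·e⁻² plus
Lennard-Jones 4ε[(σ/r)¹² − (σ/r)⁶], cutoff 1.2 nm, Lorentz–Berthelot
combination by default (geometric optional), parameters from a simple
per-atom TSV. This reproduces the *structure* of a force-field short-range
decomposition — enough to rank residue pairs and compare variants — and
makes no claim to force-field accuracy (no PME, no exclusions, no 1-4
scaling).

Salt bridges use the common geometric convention: oppositely charged side
chains (Asp/Glu carboxylate O vs Lys NZ / Arg NH,NE) with minimal N–O
distance under 4.0 Å; a pair is reported when formed in at least 50% of
window frames, with its occupancy.

Wild-type vs mutant comparison counts persistent contacts in two maps
sharing axes and reports 100·(n_wt − n_mut)/n_wt, so a planted 10 → 3 pair
difference reads as a 70% loss of contact sites.

## HSQC screening

Assignment transfer matches observed to reference peaks under the weighted
distance ((ΔδH)² + (0.15·ΔδN)²)^½ and accepts a match only when it is
mutually nearest, within tolerance, and the reference assignment is unused;
exact ties are left unassigned and flagged ambiguous. Mutual nearest is
stricter than plain nearest-neighbor transfer; it prevents double
assignment at the cost of leaving genuinely crowded regions unassigned,
which is the conservative failure mode.

The intensity screen works per titration point on SN ratios
(intensity/noise, holo over apo), excluding overlapped and proline rows.
The default flag rule is robust-outlier: ratio strictly below
median − k·MAD with k = 6 raw-MAD units (≈ 4σ under Gaussian noise). The
multiplier is large by design: a "strong reduction" is a far outlier
against the mild global line broadening every peak shares upon complex
formation, and a small multiplier would flag the noise tail of the
unaffected majority (at k = 2, about 9% of unaffected residues per table
would flag under Gaussian noise, making exact recovery of a planted set
impossible). With noiseless tables the MAD collapses to zero and the rule
degenerates to "strictly below the median", which is what the planted
attenuation examples exercise. A fixed-threshold alternative is provided.
Flagged residues are also summarized as contiguous sequence windows.

## Binding quantification

Cross-titration grids are scaled per replicate by the signal of a reference
concentration pair, averaged elementwise, and mapped to percent with
min → 0% and max → 100% (the heat-map convention; pure reference scaling is
the caller's option via the intermediate values). Competition series are
fit with a free-slope four-parameter logistic on log concentration,
initialized from data quartiles; the fitted IC₅₀ is reported as the
apparent K_D. Data that rise with competitor are rejected as
transition-free. Melt curves fit a two-state sigmoid in temperature with a
smoothed-derivative-extremum fallback; a fit is rejected as transition-free
when it fails to converge, puts the midpoint outside the measured range, or
needs an amplitude over three times the observed data range (the degenerate
shallow-slope solution a straight line produces).

Ratio normalization corrects channel intensities by their loaded fractions
(e.g. bound lane 33%, unbound 2.5% of each fraction) before forming
bound/total (default) or bound/unbound ratios, with optional background
subtraction, and scales the reference condition to 100%.

## Synthetic generators: what they emulate, and what they do not

All generators are pure functions of their arguments including the seed
(one `numpy` generator per call, no global state), so fixtures are
reproducible byte for byte.

- **Pose ensembles** use coarse templates — one Cα bead per residue plus NZ
  pseudo-atoms on the epitope lysines (ligand radius ≈ 5 Å), receptor beads
  on a 9 Å shell. True poses place an epitope atom at a distance uniform in
  [3 Å, cutoff) from a receptor atom; decoys sit on a shell at receptor
  bounding radius + 15 Å, so the decoy-to-receptor gap (≥ ~9 Å) guarantees
  filter separability by construction. Planted scores are Gaussian
  (true −20 ± 2, decoy −5 ± 2, arbitrary energy units): a gap wide enough
  that score retention at the planted prevalence is nearly noiseless,
  emulating a well-converged scoring function rather than a marginal one.
  Truth labels are recomputed from the emitted coordinates before return.
- **Contact trajectories** string bead residues far apart and move one
  carboxylate pseudo-atom per planned pair between a contact position
  (3 Å from the partner's NZ — inside both the 6 Å contact and the 4 Å
  salt-bridge rule) and a retreated position (cutoff + 8 Å), per frame,
  with independent Bernoulli or two-state Markov persistence. Unplanned
  pairs can never touch. The geometry is a contract carrier, not a
  conformational model: there is no correlated motion, no partial
  occupancy geometry, and no solvent.
- **Peak tables** scale affected residues' intensities by the attenuation
  factor and everything else by a global broadening factor (default 0.9),
  with identical noise floors across conditions, optional positional jitter
  and intensity noise, and proline/overlap flags.
- **Sigmoid curves** evaluate the exact logistic at log-spaced
  concentrations (default 1.4 nM–22.5 µM, a competition assay's competitor
  range) or linear temperatures (20–95 °C) plus Gaussian noise. With
  `n_replicates` > 1 each reported point is the mean of that many
  independent draws, emulating assays that average technical/biological
  replicates before fitting; the recovery studies use 3, matching the
  emulated protocol. This matters quantitatively: for a single unreplicated
  12-point curve at 2% noise, the Cramér–Rao bound on log IC₅₀ (~0.07)
  caps any estimator at roughly 85% of fits within 10%, so the ≥ 95%
  recovery rate the tests demand is only attainable with the replicate
  structure the real assay has.
- **Sequence pair** — the human/pig nucleotide-binding-domain pair is a
  *synthetic stand-in*: a random 218-residue sequence carrying exactly the
  six documented substitutions (S391F, S473A, A497S, R500Q, I521L, L578I)
  between the two numbering frames. It exercises the bookkeeping
  (offset-aligned Hamming comparison, substitution application and
  inversion) with the real positional structure, but it is not the real
  UniProt/PDB sequence content.

Because the generators plant exactly the structure the analyses look for,
green tests demonstrate correctness of the statistics and the plumbing —
not robustness to the messiness of real data (peak overlap crowding,
correlated frame noise, score/affinity model mismatch, partial occupancy).

## Problem sizes and numerics

Default study sizes: 100-pose ensembles (20 planted) over 10 seeds;
1000-frame trajectories analyzed over the last 500 (or the full window
where a test checks planted frequencies); 90-residue peak tables with 6
planted residues; 12-point competition curves and 60-point melt curves with
100-seed recovery studies. The full test suite and the acceptance script
each run in a few seconds on one CPU.

Numerical conventions worth knowing: Kabsch superposition via SVD with a
determinant correction (always a proper rotation); strict inequalities at
the 6 Å contact, 0.5 persistence and clash cutoffs; all sort-based
tie-breaks resolve to the lower pose/residue id so outputs are permutation
invariant; the intensity screen guards its strict threshold comparison with
a 1e-9 relative epsilon so exact ties produced by noiseless arithmetic do
not flag spuriously; PDB I/O goes through gemmi with first-altloc selection
and a hard error on insertion codes.

## Limitations

- Interaction energies are short-range and parameter-file driven; absolute
  values are not comparable to a full force-field decomposition.
- The clash filter and clustering assume identical receptor topology across
  poses; there is no structure repair or alternative-conformer handling.
- The NMR layer screens intensities only; it does not fit binding constants
  from titration shifts (shift changes in the emulated regime are
  negligible) and does no lineshape analysis.
- Sequence alignment beyond equal-length offset pairing falls back to a
  deterministic global alignment (BLOSUM62, gap open 10, extend 0.5) and is
  intended for near-identical pairs, not remote homology.
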