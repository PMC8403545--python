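# Methods

This note documents the models, parameters and numerical choices behind
`epigraft`, and what the synthetic test fixtures do and do not show about
real structures.

## Structure model and PDB handling

A chain is an ordered list of residues carrying *author* numbering
(1-based, ranges inclusive) exactly as printed in the source file, because
every range in the grafting workflow — the motif (e.g. 420–429), the graft
window (e.g. 164–173) — is expressed in author numbers. Parsing is backed
by gemmi; records are never reordered, and insertion codes are legal in
chains but illegal inside motif or window ranges, since windows are
defined by contiguous plain numbering.

Alternate locations are reduced to one conformer per atom name: highest
occupancy wins, occupancy ties go to altloc `A`, then alphabetically. This
gives a deterministic single-conformer model. Hydrogens, waters and
non-MSE heteroatoms are invisible to all geometry operations; cleaning
removes them outright and rewrites selenomethionine (MSE → MET with the SE
atom renamed SD, element sulfur) so downstream tools see a canonical
chain.

Writing emits fixed-column PDB v3.3 with 3-decimal coordinates; a
parse/write round trip preserves residue identity, numbering and
coordinates to the 0.0005 Å implied by the column width.

## Superposition and window matching

All matching uses optimal rigid superposition over proper rotations
(Kabsch, computed via SVD through `scipy`'s rotation alignment;
reflections are excluded). Degenerate point sets (collinear) still return
the least-squares optimum but are flagged with a warning.

Matching is **full-window**: the motif backbone is superposed onto every
contiguous scaffold window of exactly the motif's length. There are no
insertions or deletions and no endpoint-stub alignment — the graft is
defined as an equal-length backbone replacement, which is what makes the
chimera's residue count equal the scaffold's. Windows spanning a chain
break (consecutive Cα–Cα above 4.5 Å) or containing insertion codes are
skipped.

The backbone atom set is `{N, CA, C, O}` by default. O is included because
the carbonyl direction constrains loop pucker; the choice is a config
default (`RunConfig.backbone_atoms`), not a claim about how any particular
published search was parameterized.

Key thresholds (all in `RunConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `rmsd_threshold` | 1.0 Å | maximum window backbone RMSD for a match |
| `clash_distance` | 3.0 Å | heavy-atom pair distance counted as a clash (strict `<`) |
| `max_scaffold_size` | 150 | scaffold chains must have strictly fewer residues |
| `chain_break_distance` | 4.5 Å | consecutive Cα–Cα distance declaring a break |

The 1.0 Å match threshold and the below-150-residue scaffold limit are the
workflow's stated operating points; the 3.0 Å clash cutoff and the
zero-clash acceptance rule are this package's explicit operationalization
of "the grafted epitope must not point into the scaffold body or bury the
binding partner" — no numeric criterion is inherited, so the value is
config-exposed. Scaffold size is measured as the count of observed
residues rather than the spread of author numbers, which over-counts
nothing when chains have numbering gaps.

Match acceptance is `rmsd ≤ threshold AND clash_count = 0`. Ties order by
(rmsd, clash count, window start, scaffold id). Motif side chains are kept
verbatim in the chimera; side-chain contacts with the scaffold are
reported as a warning rather than a rejection because fixed-backbone
sequence design resolves them by construction. The chimera is renumbered
sequentially from 1 (designed sequences are conventionally numbered from
1); a sidecar map preserves the original numbering.

## Solvent accessibility and burial layers

SASA is Shrake–Rupley (via biotite) over heavy atoms with probe radius
1.4 Å, 960 sphere points per atom, single-atom van der Waals radii.
Relative SASA divides the per-residue absolute area by the residue type's
theoretical Gly-X-Gly maximum; residue types without a tabulated maximum
fall back to absolute-only with a warning and are classified boundary.

Layers use strict inequalities: core iff relative SASA < 0.15, surface iff
> 0.60, boundary otherwise. The 15 %/60 % thresholds follow common
layer-design practice and are config-exposed; burial is monotone by
construction (occluding a residue further can only lower its exposure,
hence never move it from core toward surface).

## Secondary structure

Assignment is torsion-window based, not hydrogen-bond based: helix for
φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°]; strand for φ ∈ [−180°, −80°] and
ψ ∈ [80°, 180°] or ψ ∈ [−180°, −170°] (the wrap-around); coil otherwise.
Chain termini with undefined φ or ψ are coil. Helix/strand runs shorter
than 3 residues revert to coil, suppressing single-residue artifacts. This
is simpler and fully deterministic compared to DSSP-style assignment; it
agrees with it on ideal geometry and can differ on distorted or bifurcated
hydrogen-bond patterns — a deliberate trade of sensitivity for
reproducibility.

## Design specification

Motif positions are never designable. Every other position gets the
palette looked up by its (layer, secondary structure) cell, with the
native residue always included. The default palette table (core:
hydrophobics, plus small residues in loops; surface: polar/charged plus
helix/strand formers; loops admit G and P; boundary: broad) is an editable
argument — it encodes standard layer-design practice, not a published
table.

The emitted weight overrides are exactly
`aa_rep 1.0`, `aspartimid_penalty 1.0`, `buried_unsatisfied_penalty 1.0`,
`approximate_buried_unsat_penalt 5.0`. The first and last names do not
match standard scoring-term vocabularies (`aa_rep` is plausibly a
repulsive-term weight; the last looks truncated); they are emitted
verbatim so the file matches the workflow they came from, and any renaming
is left to the consumer.

The consensus line over a design set follows the Clustal convention:
`*` identical column, `:` column within one strong conservation group,
`.` weak group, space otherwise; the groups are the standard Clustal sets
declared in `design_prep`.

## Evaluation

A decoy funnel summary takes (score, RMSD-to-design) points and a
baseline score (the relaxed design's own score, i.e. the presumed energy
floor). `funnel_success` requires the best-scoring decoy (score ties
broken by lower RMSD) to lie within `rmsd_cut` = 2.0 Å of the design *and*
to score within `score_margin` = 1.0 energy units of the baseline. This is
a deterministic operationalization of the visual "funnel-shaped plot"
judgment; both knobs are config-exposed, and the low-score tail statistic
(`low_score_fraction_rmsd`, default q = 1 %) is reported alongside.
Note that `min_rmsd ≤ rmsd_of_best_score` is *not* an invariant — its
failure is precisely a failed funnel.

Motif fidelity over a model ensemble is reported in two modes: *local*
(motif superposed on motif — how well the epitope's internal geometry is
reproduced) and *global* (model superposed on the design over the full
backbone, then motif RMSD without refitting — how well the epitope is
held in place). Local ≤ global per model by optimality. Both are reported
because an ensemble-average motif RMSD is ambiguous about which of the
two it means.

Trajectory metrics remove rigid motion per frame before the RMSD and
compute the mass-weighted radius of gyration

`Rg = sqrt( Σᵢ mᵢ ‖rᵢ − r_com‖² / Σᵢ mᵢ )`

with element masses over heavy atoms; frames come from multi-MODEL PDB
or a plain coordinate array.

## Synthetic fixtures

The generator builds backbones by internal-coordinate chain extension
(NeRF) with ideal geometry: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å,
ω = 180°, canonical torsions −57°/−47° (helix) and −139°/+135° (strand);
coil torsions are drawn per residue from a seeded region
(φ ∈ [−78°, −45°], ψ ∈ [20°, 160°]) chosen to lie outside both assignment
windows, with a ψ range wide enough that seeded coil segments are
geometrically diverse — which is what makes a planted coil motif
effectively unique in a scaffold. Poly-positional side chains are a single
ideal CB (absent for glycine) so SASA and clash logic have heavy atoms to
work with. Everything is bit-reproducible from (spec, seed).

Planted graft sites are calibrated by deforming the window with a twist
whose angle varies smoothly along the chain and vanishes at both ends
(locally near-isometric, junctions pinned), bisecting the amplitude until
the optimal-superposition RMSD hits the target within 0.02 Å. Ground-truth
RMSDs come from an independent closed-form quaternion (Horn) solver, never
from the SVD path under test; clash-count ground truths are verified by
brute-force all-pairs distances. Binding-partner decoys place an exact
number of atoms strictly inside the clash cutoff (each with a unique
scaffold partner) and all remaining atoms at least twice the cutoff away,
with bounded retries and an error if the geometry cannot be realized.

What passing fixture tests show: the search, screening, grafting, layer,
and evaluation machinery is geometrically correct, deterministic and
calibrated. What they do not show: behaviour on real crystallographic
pathologies (alternate conformations beyond altloc policy, missing loops,
non-ideal geometry), nor that any particular real scaffold accepts any
particular real motif — those checks run against downloaded PDB entries
where network access permits.

## Problem sizes and determinism

Default test and acceptance runs use 26-residue donors, 60-residue
scaffolds, 10-residue motifs and decoy clouds of 80–200 points — sizes
chosen so every quantity is recomputed from scratch in seconds while
still exercising every code path (window scans of ~50 windows × 40 atoms,
clash screens of a few thousand atom pairs). All randomness flows from a
single integer seed; the pipeline writes a manifest with a config
snapshot and SHA-256 checksums of inputs and outputs, and identical
inputs yield identical manifests.

## Known limitations

- No backbone remodeling or loop closure: a motif either fits a window
  rigidly or it does not.
- Single-segment motifs only; no multi-segment epitopes.
- Torsion-based secondary structure, not hydrogen-bond based.
- The funnel criterion is a threshold rule on one point of the decoy
  cloud plus a baseline gap; it does not model the full score–RMSD joint
  distribution.
- mmCIF is not read; crystallographic symmetry is not expanded; hydrogens
  are never placed.
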