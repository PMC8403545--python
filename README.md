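# epigraft

Epitope grafting onto protein scaffolds: excise a short structural motif
from a donor protein, find a small scaffold protein whose backbone can
carry it, graft it, and prepare everything an external fixed-backbone
sequence designer and a folding evaluation need.

## The problem

Some therapeutic designs need a protein that displays a single epitope —
a short contiguous backbone segment of a larger molecule — in its native
three-dimensional shape, without the rest of the donor protein. The worked
case this toolkit grew from is the FG loop of the human IgE antibody
(PDB 2Y7Q, chain B, residues 420–429, sequence `VTHPHLPRAL`), which sits
next to the FcεRIα receptor binding site: displayed on a small
*Staphylococcus aureus* EAP scaffold (PDB 1YN3), it becomes a candidate
immunogen against IgE itself.

The computational core is geometric:

1. **Excision** — copy the motif residues (backbone + side chains) in the
   donor frame, together with the full binding-partner chain (the receptor
   α chain) for the clash test.
2. **Scaffold library** — split PDB entries into chains, keep chains with
   fewer than 150 residues, strip waters/ions/ligands, rewrite
   selenomethionine (MSE → MET, SE → SD), and validate backbone
   completeness and chain continuity.
3. **Window search** — superpose the motif backbone (N, CA, C, O) onto
   every contiguous equal-length scaffold window (Kabsch, proper rotations
   only). A window *matches* when the optimal RMSD is ≤ 1.0 Å:

   `RMSD(X, Y) = min over rigid T of sqrt( (1/N) Σᵢ ‖T(xᵢ) − yᵢ‖² )`

4. **Clash screen** — carry the binding partner along by the same rigid
   transform and count heavy-atom pairs against the scaffold (outside the
   window) closer than 3.0 Å; an accepted graft has zero.
5. **Graft** — equal-length backbone replacement: the window residues are
   removed, the transformed motif residues inserted, the chimera
   renumbered from 1 with per-residue provenance.
6. **Design preparation** — classify every chimera position by burial
   layer (relative solvent accessibility: core < 15 %, surface > 60 %) and
   torsion-based secondary structure (H/E/C), fix the motif, and emit a
   resfile-style per-position palette plus the energy-weight overrides for
   the external designer (`aa_rep 1.0`, `aspartimid_penalty 1.0`,
   `buried_unsatisfied_penalty 1.0`, `approximate_buried_unsat_penalt 5.0`).
7. **Evaluation** — decoy funnel summaries (score vs RMSD against a
   relaxed-design baseline), motif-fidelity RMSD across model ensembles,
   and per-frame RMSD / radius of gyration over coordinate trajectories.

Sequence design itself (rotamer packing) and folding simulation are
external; this package prepares their inputs and evaluates their outputs.

## Worked example

The package ships a fixture generator that builds a donor/scaffold pair
with a known planted graft site, so the whole pipeline can be exercised
without downloads:

```
$ epigraft fixtures --out fx --seed 11 --target-rmsd 0.4
fixture pair -> fx (planted site 26, rmsd 0.403 Å)

$ epigraft run --donor fx/donor.pdb --motif SYND11:D:9-18+X \
               --scaffolds fx/scaffolds --out run
INFO epigraft: grafted SYNS11_A at 26 (rmsd 0.403 Å, 0 clashes)
1 accepted graft(s) -> run
```

The motif spec `SYND11:D:9-18+X` reads: donor entry SYND11, chain D,
author residues 9–18 inclusive, carrying chain X as the binding partner.
The search report confirms the planted site was recovered at its
calibrated RMSD and passed the clash screen:

```
$ cat run/report.tsv
scaffold_id   window_start  rmsd    clash_count  accepted
SYNS11_A      26            0.4025  0            True
```

`run/` also contains the grafted chimera PDB, a per-position design spec
(`FIXED` rows are the motif block; `PIKAA` rows list the layer- and
secondary-structure-restricted palette):

```
1 G PIKAA DEGHKNPQRST surface C
2 A PIKAA ADEGHKNPQRST surface C
3 V PIKAA ADEHIKLMNQRSTVWY boundary H
...
```

a weights file with the four design-time overrides, and `manifest.json`
with the config snapshot and SHA-256 checksums of all inputs and outputs
(identical inputs reproduce identical manifests).

With real structures the same workflow is
`epigraft search --db DB --donor 2Y7Q.pdb --motif 2Y7Q:B:420-429+A`,
after `epigraft builddb --in pdb_dir --out DB --max-size 150`.

The library surface mirrors the CLI: `parse_pdb`, `excise_motif`,
`scan_scaffold`, `clash_screen`, `graft`, `build_design_spec`,
`funnel_summary`, `motif_fidelity`, `trajectory_metrics`; see
`docs/methods.md` for the model details and parameter rationale.

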