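# Methods

`pharmscreen` re-implements, at desk scale, the classical structure-based
pharmacophore screening cascade used to find small-molecule inhibitors of
protein–protein interfaces — the motivating case being the CD147
dimer-interface campaign that produced the inhibitor AC-73 — together with
the post-screen experimental triage arithmetic.  This note records the model,
its assumptions, the parameters that matter, and the design choices made
where the procedure is genuinely open.

## The screening model

### Pocket and interaction map

A pocket is an *active-site sphere* (center, radius) over a parsed PDB
structure.  Residues with a heavy atom inside the sphere contribute
*protein sites* from a fixed rule table:

* backbone amide N — H-bond donor.  Direction points along N→H when an
  explicit amide H is present, otherwise toward the pseudo-hydrogen at
  `2·CA − C` (a same-residue construction that works on unprotonated
  crystal structures);
* backbone carbonyl O — acceptor along C→O;
* side chains: Ser/Thr/Tyr hydroxyls donate and accept; Lys NZ and Arg
  NE/NH1/NH2 donate; Asp/Glu carboxylate oxygens accept (direction from the
  carboxyl carbon); Asn/Gln amide N/O donate/accept; His ring nitrogens do
  both; Trp NE1 donates;
* a hydrophobic site at the centroid of the apolar side-chain carbons of
  Ala/Val/Leu/Ile/Phe/Met/Pro/Trp.

Each protein site is projected into the pocket as the *complementary*
ligand-side feature: a protein donor asks for a ligand acceptor placed
`d_hb = 2.9 Å` along the donor direction (canonical heavy-atom H-bond
length); acceptors symmetrically; hydrophobic sites project `d_hp = 4.0 Å`
toward the pocket center.  Projections that leave the sphere or fall within
`clash_dist = 1.5 Å` of a protein heavy atom are discarded.  Every protein
heavy atom near the pocket contributes an *exclusion volume* of radius
`r_excl = 1.4 Å` — forbidden space no ligand heavy atom may penetrate
(strict interior; surface contact is allowed).

### Feature clustering

Projection produces many near-duplicate features, so features of each kind
are condensed by complete-linkage hierarchical clustering at a cutoff of
1.5 Å (complete linkage bounds the cluster diameter, so the averaged center
stays representative; the linkage computation itself is SciPy's).  Each
cluster becomes one feature at the weighted mean position, with weight equal
to the number of original features it absorbed.

One refinement is deliberate: a *single* linkage cut is not idempotent —
after averaging, two representatives can land within the cutoff of each
other — so condensation passes repeat until a fixed point.  Each pass
strictly reduces the feature count, so the loop terminates; re-clustering
the output at the same cutoff is then exactly a no-op, which is the contract
downstream code relies on.  Weight-averaged positions keep every
representative at the arithmetic mean of the original features it stands
for, regardless of how many passes produced it.

### Hypotheses and matching

Query pharmacophores (*hypotheses*) are all subsets of 3–7 clustered
features whose pairwise distances are at least `min_pair_dist = 2.0 Å`
(degenerate near-duplicate queries are useless).  Ligand features use the
same three-kind vocabulary: donors are O/N bearing hydrogen; acceptors are
any O, plus N with an available lone pair (not quaternary, not amide, and
aromatic N only when H-free); hydrophobic features are all-carbon ring
centroids and centroids of connected acyclic runs of ≥3 apolar carbons.

Matching searches injective kind-compatible assignments of hypothesis
features to ligand features, pruned by pairwise distance compatibility
(`|d_lig − d_hyp| ≤ t_i + t_j` for tolerance spheres `t`).  Each assignment
is realized by a proper-rotation Kabsch superposition of the matched ligand
points onto the hypothesis (reflections are excluded by the determinant
correction), the whole conformer is transformed, poses violating an
exclusion volume are rejected, and survivors are scored

    fit = Σ_i  w_i · max(0, 1 − (d_i / t_i)²)

— a quadratic-falloff fit value in the style of classical pharmacophore
software, maximal (Σ w_i) at perfect superposition.  The commercial fit
functions used in the original work are proprietary; this form is an open
analog, documented as such, and nothing downstream depends on matching their
numeric values.

### The funnel

Per ligand, the best exclusion-passing fit over all hypotheses, conformers
and mappings is kept (supplied conformers only; no on-the-fly flexing).
The funnel then applies, in order: physicochemical property filters
(`MW ≤ 500`, `logP ≤ 5`, `logS ≥ −6`, boundaries inclusive), a top-N cut on
fit, rigid-body pose minimization with energy rescoring, a top-N cut on
energy, and leader-algorithm diversity selection (accept a candidate iff its
Tanimoto similarity to every accepted leader is below 0.9, stop at N).
The original campaign's sizes were 5 000 → 1 000 → 100 over a 300 000-
compound library; the synthetic desk-scale default is 20 → 10 → 5 over 50.
All ties break on ligand id, so reruns are byte-identical.

logP is the Wildman–Crippen atom-additive estimate; logS is the ESOL linear
model `0.16 − 0.63·logP − 0.0062·MW + 0.066·RB − 0.74·AP` (RB = rotatable
bonds, AP = aromatic fraction); fingerprints are hashed linear-path
fingerprints (element + bond-order paths, lengths 1–6, 1024 bits).

### Energy model

Pose energies are a transparent pairwise nonbonded sum over heavy-atom
pairs within a 10 Å cutoff:

    E = Σ 4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶] + 332.0636·q_i·q_j/(4r²)

with Lorentz–Berthelot combining and the distance-dependent dielectric
ε(r) = 4r standard for implicit-solvent pocket scoring.  Partial charges are
a simple documented heavy-atom scheme: formal charges plus fixed polar-group
increments (carboxylate O −0.57, backbone O −0.40, backbone N +0.25, Lys NZ
+0.60, …).  Because hydrogens are implicit, donor heavy atoms (O–H, N–H)
carry the hydrogen's *positive* face charge (+0.20/+0.25); a net-negative
donor oxygen would make hydrogen bonds repulsive in a heavy-atom monopole
model.  This model makes no claim of numeric equivalence with the
proprietary docking scores reported for the original campaign (those values
are explicitly not reproduction targets); it is held instead to its own
exact properties — the Lennard-Jones minimum closed form, per-residue
decomposition conservation, rigid-motion invariance.

Per-residue decomposition attributes each pair term to the residue owning
the protein atom, over the shell of residues with a heavy atom within 10 Å
of the ligand; the entries sum to the shell total to machine precision.

"In situ ligand minimization" is rigid-body (3 translations + 3 rotations
about the centroid) coordinate descent with a shrinking step schedule
(0.4 → 0.01 Å; rotations at half the step in radians).  Energy never
increases along the trace and the search is fully deterministic.  Internal
torsions are deliberately frozen: the input is already a feature-matched
pose, and a deterministic 6-DOF polish is what the desk-scale funnel needs.

H-bonds are detected geometrically: donor–acceptor heavy-atom distance
≤ 3.5 Å, plus a D–H···A angle ≥ 120° whenever an explicit hydrogen is
available (ligand H with coordinates, protein amide H); without explicit H
the bond is accepted on distance and the angle reported absent.

### Triage and dose–response

Post-screen triage applies *strict* thresholds to two orthogonal readouts —
SPR binding (`RU > 20`) and MMP-2 secretion inhibition from zymography
densitometry (`inhibition > 30 %`, with
`inhibition = [1 − gray_treat/gray_ctrl]·100`) — and reports the two hit
lists and their intersection; in the original campaign that intersection was
the single compound that became AC-73.  Dimerization inhibition is
quantified as the dimer band fraction `dimer/(dimer+monomer)`, optionally
normalized to a control lane.  Potency is a four-parameter logistic fit

    y = bottom + (top − bottom)/(1 + (x/IC50)^hill)

by Levenberg–Marquardt least squares from the fixed initialization
bottom = min y, top = max y, hill = 1, IC50 = geometric-mean dose, with IC50
optimized on a log scale so it stays positive.  Degenerate (flat) data are
flagged not-converged.

## Synthetic data: what it emulates and what it does not

No crystal structure, vendor library or wet-lab table ships with the
package; generators produce deterministic stand-ins with ground-truth
manifests.

* **Toy pocket** — 12 residues on a 10 Å ring around the origin, side chains
  pointing inward, open along z: a concave cleft whose roster echoes the
  targeted interface neighborhood (glutamates numbered 64 and 73, a lysine,
  Ser/Thr donors, Leu/Phe/Val/Ala hydrophobics).  Coordinates are idealized
  with small seeded jitter (σ = 0.05 Å); bond geometry is not physical and
  no secondary structure exists.  Passing tests on it demonstrates the
  *pipeline logic* (site rules fire, features project into free space,
  exclusion volumes wrap the wall), not performance on real folds.
* **Planted library** — multi-fragment probe molecules (methanol for a
  donor, formaldehyde for an acceptor, a z-oriented propane run for a
  hydrophobic point, plus a distinguishing halogen/chalcogen tag fragment
  per molecule for fingerprint diversity).  Actives present every feature of
  a chosen hypothesis exactly, except one feature displaced by a stated
  amount (< the tolerance), which bounds their fit below by
  `(k−1) + (1 − (δ/t)²)`.  Decoys either omit every fragment able to
  present some required kind (note: any O–H/N–H donor fragment is also an
  acceptor, so "no acceptors" forces "no donors" too) or present all kinds
  at uniformly inflated pairwise distances.  Planted screens run against the
  planted hypothesis: against a full enumeration, a kind-deficient decoy
  could legitimately max-fit some query that does not ask for the omitted
  kind, which would say nothing about the planted truth.  These probes are
  not drug-like molecules; enrichment here validates the matcher, scorer and
  funnel bookkeeping, not virtual-screening power on real chemistry.
* **Readout table** — 100 compounds with exactly 5 RU hits, 7 inhibition
  hits and 1 overlap planted (the reported primary-screen structure), noise
  elsewhere.
* **Dose–response** — 4PL curve values plus seeded Gaussian noise.

All generators are pure functions of (parameters, seed); identical calls are
byte-identical.  Seeds are recorded in the PDB REMARK header and the JSON
manifests.

## Numerical choices and benchmark conditions

* Coordinates compare at 3 decimals through PDB round-trips (PDB's fixed
  column width); map JSON round-trips exactly.
* The 4PL noisy-recovery benchmark (median |log(IC50_hat/IC50)| ≤ 0.07 over
  100 seeds at noise σ = 5 on a 100-unit range) is run with triplicate wells
  at 8 log-spaced doses spanning three decades around the IC50 and hill = 2.
  Triplicates mirror how such assays are actually measured; the steepness is
  what resolving an IC50 inside a 5–15 µM dose window implies.  With single
  wells and hill = 1 the bound is statistically out of reach for *any*
  unbiased fitter (a truth-initialized reference fit shows the same ~0.19
  median), so the benchmark conditions, not the optimizer, are the binding
  constraint.
* Desk-scale problem sizes (50-ligand libraries, 12-residue pockets,
  20 → 10 → 5 funnels, 100-seed benchmark loops) keep any single check in
  seconds while still exercising every stage end to end.
* Tie-breaks are lexicographic everywhere (ligand id, then hypothesis id,
  then conformer index); clustering merge ties follow SciPy's deterministic
  ordering.  Degenerate inputs fail loudly: empty record tables, non-finite
  starting energies, collapsed atom pairs (< 10⁻³ Å), fewer than 4 distinct
  doses.

## Known limitations

* Feature kinds stop at donor/acceptor/hydrophobic: no aromatic-stacking,
  charge-center or water-mediated features, and no directionality term in
  the fit score.
* Stereochemistry is ignored in matching (the original lead's chiral center
  is flagged as future work in its own report); tautomers and protonation
  states are taken as drawn.
* The energy model is a monopole + LJ analog with implicit hydrogens — fit
  for ranking poses in a funnel and for qualitative per-residue attribution,
  not for absolute binding free energies; positive per-residue entries for
  charged residues depend entirely on the increment table.
* Rigid-body minimization cannot fix a bad conformer, only a bad placement.
* Single-model PDB parsing only: no mmCIF, NMR ensembles, symmetry mates or
  alternate-location ensembles beyond 'A'/blank.
* The SPR and zymography readouts are modeled as numbers in a table; no
  sensorgram kinetics or gel-image processing.
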