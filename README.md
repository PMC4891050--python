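# pharmscreen

Structure-based pharmacophore virtual screening and hit triage, at desk
scale.

Protein–protein interfaces are hard drug targets: the CD147 dimer interface
that motivates this package has no deep enzymatic site, yet disrupting
dimerization blocks downstream MMP-2 signaling in hepatocellular carcinoma.
The classical attack is a structure-based pharmacophore cascade — derive an
interaction map from the pocket itself, screen a large library against
3–7-feature sub-pharmacophores, rescore and diversify, and push a small
final set into binding (SPR) and functional (zymography) assays, keeping
the compounds that pass both.  `pharmscreen` implements every computational
stage of that cascade as a reusable, fully deterministic Python library
with a CLI, plus synthetic-data generators so the whole funnel is testable
without a commercial library or a wet lab.

## The method in brief

1. **Interaction map.**  Pocket residues contribute H-bond donor/acceptor
   and hydrophobic sites (fixed rule table); each site projects its
   *complementary* ligand feature into the pocket (2.9 Å along H-bond
   directions, 4.0 Å toward the center for hydrophobics).  Protein heavy
   atoms become exclusion volumes (r = 1.4 Å).  Near-duplicate features are
   condensed by complete-linkage clustering (cutoff 1.5 Å).
2. **Hypotheses.**  All 3–7-feature subsets with pairwise distances ≥ 2 Å.
3. **Matching + fit.**  Injective, kind-compatible feature assignments with
   distance pruning; Kabsch superposition (proper rotations only);
   exclusion check; fit value `Σ wᵢ·max(0, 1 − (dᵢ/tᵢ)²)`.
4. **Funnel.**  Property filters (MW ≤ 500, logP ≤ 5, logS ≥ −6) → top-fit
   cut → rigid-body minimization + pairwise LJ/Coulomb rescoring (ε(r)=4r,
   per-residue decomposition, H-bond report) → top-energy cut →
   leader-algorithm Tanimoto diversity pick.
5. **Triage.**  Strict thresholds on the experimental readouts
   (`RU > 20`, `inhibition > 30 %` where
   `inhibition = [1 − gray_treat/gray_ctrl]·100`), intersection of the two
   hit lists, densitometry dimer fractions, and 4PL dose–response fitting
   `y = bottom + (top − bottom)/(1 + (x/IC50)^hill)`.

`docs/methods.md` documents the model, parameter defaults, the synthetic
generators and their limits, and the open design choices.

## Worked example

Triage the five-candidate readout table from the original campaign
(`compound_id,ru,inhibition` CSV):

```
$ pharmscreen triage --records records.csv
list	count	ids
ru_hits	3	AF-399/15392135,AN-979/15448127,AN-465/42834501
inhibition_hits	3	AN-465/42834501,AG-205/13358154,AG-205/12140154
intersection	1	AN-465/42834501
# 5 records; RU > 20; inhibition > 30%
```

Three compounds bind (RU > 20), three suppress MMP-2 secretion (> 30 %),
and exactly one — AN-465/42834501, the compound later named AC-73 — does
both.  Its properties, computed from the structure implied by its published
IUPAC name:

```
AC-73: formula C21H21NO2  MW 319.404 Da  logP 3.88  logS -4.43
```

(The vendor catalogue prints 319.36942 Da; the standard-atomic-weight sum
agrees to 0.01 %.)

Run the synthetic end-to-end funnel (toy pocket, 5 planted actives + 45
decoys, funnel 20 → 10 → 5):

```
$ pharmscreen run --out-prefix demo
final set: ['ACT-003', 'ACT-005', 'ACT-004', 'ACT-002', 'ACT-001']

$ column -t demo_hits.tsv
ligand_id  hypothesis_id  conformer  fit     energy_kcal_mol
ACT-003    0-5-8          0          2.9977  -7.4904
ACT-005    0-5-8          0          2.9783  -7.2754
ACT-004    0-5-8          0          2.9395  -7.2685
ACT-002    0-5-8          0          2.9590  -6.6552
ACT-001    0-5-8          0          2.9317  -6.2545
```

All five planted actives reach fit ≈ 3 (the maximum for a 3-feature query;
each active has one feature deliberately displaced by 0.5 Å, hence the
small deficit), every kind-deficient or geometry-broken decoy fails to
match at all, and the funnel report (`demo_funnel.tsv`) shows the counts
50 → 50 → 5 → 5 → 5 → 5.  The run also writes the top hit's per-residue
energy table and H-bond report.

Other subcommands: `pocket-map`, `enumerate`, `screen`, `score`,
`diversity`, `fit-ic50`, `simulate pocket|library|screen-table|dose-response`,
`config --dump`.

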