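# Methods

## Problem and model

`abddg` predicts the change in antibody–antigen binding free energy caused by
one or several simultaneous point mutations. Experimental affinities are
dissociation constants; they are converted to free energies with

    ΔG = RT·ln(K_D),        R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹

and a mutation's effect is expressed as

    ΔΔG = ΔG_wild − ΔG_mutant   (kcal/mol),

so a **positive** ΔΔG means the mutant binds **more tightly**. The default
assay temperature when a source table omits it is 298 K.

The predictor is an ensemble of extremely randomized regression trees
(scikit-learn `ExtraTreesRegressor`, 300 trees, unlimited depth, explicit
seed) over a fixed, versioned feature schema. Feature families, in schema
order:

1. **Graph-based signatures (cutoff scanning matrix).** The environment of
   the mutated site(s) — every heavy atom within 10 Å of any heavy atom of
   any site — is summarized as cumulative counts of pharmacophore-class pairs
   at increasing distance thresholds. For each unordered atom pair at
   separation d and each grid edge e, the pair adds one count to every
   distinct unordered class-pair cell induced by the two atoms' class sets
   whenever d ≤ e. The grid runs from `d_min` to `d_max` inclusive in `step`
   increments (defaults 1.0–10.0 Å, step 1.5 Å). The first edge sits at
   `d_min` itself; with heavy atoms it is almost always a zero column and
   exists to keep the grid uniform. Eight atom classes are used
   (hydrophobic, positive, negative, H-bond acceptor, H-bond donor, aromatic,
   sulfur, neutral); an atom may carry several. The class table lives in
   `src/abddg/data/pharmacophores.tsv`, authored from standard amino-acid
   chemistry: apolar carbons are hydrophobic, amide/backbone N–H donors,
   carbonyl O acceptors, LYS NZ / ARG guanidinium N / HIS ring N positive,
   ASP/GLU carboxylate O (and OXT) negative, ring atoms of PHE/TYR/TRP/HIS
   aromatic, CYS SG and MET SD sulfur, and polar carbons with no other role
   neutral. Proline's N carries no hydrogen and is classed neutral. For
   multi-site mutations one signature is computed over the **union**
   environment of all sites, which captures neighbourhood overlap between
   nearby sites; it is not a sum of per-site signatures.
2. **Pharmacophore changes**: per-class atom-count difference between the
   idealized mutant and wild-type residues, summed over sites.
3. **Interaction deltas**: mutant − wild-type counts of typed non-covalent
   contacts, per type, in three scopes (whole complex, across the
   antibody–antigen interface, involving a mutated site). Contact typing is
   heavy-atom geometric: hydrogen bond = donor-class N/O/S to acceptor-class
   N/O at 2.5–3.5 Å; generic polar = the same donor/acceptor pairs out to
   4.0 Å when hydrogen-bond geometry fails; ionic = opposite formal-charge
   atoms ≤ 4.0 Å; aromatic–aromatic = ring centroids ≤ 6.0 Å; cation–π =
   charged atom to ring centroid ≤ 6.0 Å; hydrophobic = apolar C–C ≤ 4.5 Å;
   van der Waals = heavy atoms within the sum of their radii + 0.5 Å and not
   otherwise typed. Covalent bonds are inferred by distance (≤ 1.9 Å, 2.2 Å
   when sulfur is involved); bonded and 1-3 pairs are never contacts. A pair
   may legitimately carry several types (a salt bridge is also counted as a
   hydrogen bond when its distance fits).
4. **Solvent accessibility deltas**: mutant − wild-type SASA at the mutated
   sites, over the whole complex, and of the interface-buried area
   (sum of the two sides' isolated SASAs minus the complex SASA). SASA is
   Shrake–Rupley sphere sampling with per-element van der Waals radii,
   a 1.4 Å probe and a deterministic golden-spiral lattice of 960 points per
   atom. Determinism makes results exactly reproducible; the price is that
   rotating a structure changes values within the sampling tolerance
   (≈0.5 % at the default density, converged to <2 % against 10 000 points).
5. **Mutation geometry**: min/mean/max pairwise heavy-atom distance between
   mutated sites (all 0 by convention for single-site mutations, with an
   explicit `n_sites` column so trees can condition on it), and min/mean
   heavy-atom distance from the sites to the binding partner.
6. **Evolutionary scores**: PAM30 substitution scores (sum and min over
   sites; the matrix is Biopython's bundled NCBI PAM30) and, when PSI-BLAST
   ASCII PSSMs are supplied, wild-type/mutant/delta log-odds (sum over sites,
   plus the per-site minimum delta) with a missingness indicator. PSSMs are
   *consumed*, never computed — running PSI-BLAST is an external,
   non-deterministic dependency — and profile positions map onto structure
   residues only by exact sequence match; any mismatch is an error, never a
   silent shift. Missing PSSM columns are median-imputed at training time.

## Mutant modelling

Mutants are modelled directly on the wild-type structure by incremental
side-chain template grafting, one point mutation at a time in list order.
Backbone atoms (N, CA, C, O) never move; the idealized residue template
(heavy atoms of the Chemical Component Dictionary entry bundled with biotite)
is least-squares superposed on the backbone N–CA–C frame and contributes all
atoms beyond the backbone, chi angles as in the template. There is no rotamer
search and no energy minimization: the features read from these models are
coarse counts and areas, not energies, and a deterministic mutator keeps
every downstream quantity exactly reproducible. Glycine mutants correctly
retain no atoms beyond the backbone; proline/glycine design candidates are
flagged for backbone strain rather than excluded.

Structures are read from PDB text: model 1, ATOM records of the 20 standard
residues, hydrogens and HETATM/waters dropped, altlocs resolved to the
highest-occupancy conformer (alphabetical on ties), author numbering with
insertion codes preserved verbatim (antibody loop numbering needs them).
Mutations are written `CHAIN.WT<number><icode?>MT`, sites joined by `;`,
one multi-mutation per line — e.g. `H.Y33A;L.S52W`, or `H.A100BY` for an
insertion-code site.

## Dataset curation

* **Reverse-mutation augmentation.** Experimental sets are skewed towards
  destabilizing mutations (mean ΔΔG around −1 kcal/mol), which biases a
  regressor. For every eligible single-point record a hypothetical reverse
  record is added: the modelled mutant structure becomes the wild-type
  context (features are recomputed there, not negated), letters swap and ΔΔG
  negates. Eligibility is |ΔΔG| < 2 kcal/mol (strict), because reversing a
  binding-compromising mutation is not physically meaningful; a signed
  variant of the filter is available as config.
* **Additive vs synergistic.** A multi-point record whose constituent
  singles are all measured is *additive* when its ΔΔG is within 1 kcal/mol of
  the sum of the single effects, *synergistic* beyond that, *unlabelable*
  when a single is missing.
* **Classification bands.** Increasing = ΔΔG > 0.5 kcal/mol, decreasing =
  ΔΔG ≤ −0.5; the open band between is reported as neutral. Binary metrics
  drop neutral truths by default, or split the band at 0 under an explicit
  flag.
* **Non-binders** (mutations abolishing binding) carry no ΔΔG, are excluded
  from regression training by a container invariant, and are evaluated as a
  classification-only set.

## Training and validation

Greedy forward feature selection adds, at each step, the feature maximizing
cross-validated Pearson correlation (5-fold, seeded, the same folds for every
candidate) and stops when the gain is ≤ ε. The default ε = 1e-3 favours
exhaustiveness; small tolerances admit occasional noise features, so parsimony
studies should raise ε to ~0.01. Ties break on schema order, which makes
selection deterministic. Selection size is data-dependent and reported, not
enforced.

Cross-validation never leaks structural context: in leave-one-complex-out
every record of a complex (including its reverse records) occupies one fold;
in stratified k-fold (stratified by ΔΔG quartile) records are grouped so that
a forward record and its hypothetical reverse always co-travel. When k
exceeds the smallest stratum (e.g. leave-one-out), stratification is dropped
and only the grouping constraint is kept. Metrics: Pearson, Spearman,
Kendall tau-b, RMSE, and MCC/F1/AUC at the ±0.5 kcal/mol bands with
increasing as the positive class. On constant input the correlations are
reported as NaN while RMSE is still computed.

Design mode enumerates all C(n, order) × 19^order double or triple mutations
of one side's interface residues (heavy-atom contact within 5.0 Å of the
opposite partition by default — a common contact definition, chosen here,
not prescribed) and streams them through the model, keeping only two bounded
heaps of the top increasing/decreasing candidates, so memory is independent
of candidate count. Combinations are scored jointly through the same
multi-site aggregation as prediction mode, not by summing single-site
predictions.

**Multi-site aggregation** is the one genuinely open design area: the model
trains on single-point records and predicts multi-point ones. Here one mutant
structure carries all sites; delta features compare wild type against that
final mutant; per-site scalars (evolutionary scores, distances) are combined
as sum/min/mean columns so that feature selection, not a hard-coded rule,
decides what matters. The aggregation is explicit config, declared rather
than inferred.

## Synthetic data

`fixtures` makes every stage testable offline. `make_toy_complex` builds
ideal-geometry polypeptides (natural-extension-reference-frame backbone at
φ = −140°, ψ = 135°, template side chains) and places two chains at a
requested minimum heavy-atom approach (default 4.5 Å, achieved within
0.1 Å by a bracketing root solve on the separation). `make_synthetic_dataset`
draws mutations on such complexes (30 % multi-point, 2–3 sites) and plants a
known effect law: true ΔΔG is linear in five z-scored *computed* features
(hydrophobic pharmacophore delta, PAM30 sum, distance to partner, total SASA
delta, site count) plus one pairwise interaction term, rescaled to a 1.5
kcal/mol signal spread, centred on −1 kcal/mol to mimic the destabilization
skew of experimental sets, with Gaussian noise of σ = 0.3 kcal/mol — enough
noise that memorization cannot explain recovery, little enough that a tree
ensemble can succeed. K_D pairs are back-computed from the planted ΔΔG at
298 K so the full K_D → ΔG → ΔΔG curation path is exercised. Non-binders are
planted as the most destabilizing candidates of an extra pool; additive and
synergistic multi-records are assembled from existing singles with offsets
drawn inside/outside the 1 kcal/mol tolerance. Everything is a deterministic
function of the seed.

What the toy complexes are **not**: folded proteins. They have no packed
core, no realistic rotamers, no hydrogens, and their interfaces are flat
strand-on-strand contacts. Passing tests therefore demonstrate the
correctness of the machinery (geometry, counting, curation, leakage control,
learnability of a feature-expressed signal) — not predictive accuracy on real
antibody–antigen complexes, which depends on curated experimental datasets
supplied by the user.

## Numerical choices and degenerate inputs

* Signature bin membership uses d ≤ edge with a 1e-9 tolerance; counts are
  exact integers, so rigid-body motion leaves signatures bit-identical.
* Kabsch superposition handles the 3-point backbone frame; the reflection
  branch is guarded by the determinant sign.
* Contact windows are validated on every detected contact.
* The identity "mutation" (wild type against itself) is a supported test
  hook: all delta families are exactly zero.
* Zero-variance targets are rejected at training; fewer than 10 rows are
  rejected; a trained model refuses feature input produced under a different
  schema hash.
* Distance features of single-site records use a 0 Å sentinel; trees separate
  it via `n_sites`.

## Problem sizes used by the shipped experiments

The acceptance pipeline (`scripts/acceptance.py`) uses six 24-residue toy
complexes and 500 synthetic records (plus 5 planted non-binders and 6 planted
additive/synergistic multi-records), a 75/25 held-out split, and the full
300-tree ensemble; the leave-one-complex-out and 5-fold evaluations run on
the ~350 single-point records. These sizes were chosen to make the recovery
experiment statistically meaningful while keeping the whole pipeline
re-runnable in a few minutes on one CPU.

## Known limitations

* Contact typing is a heavy-atom approximation of hydrogen-aware rule sets;
  donor/acceptor geometry (angles) is not checked.
* The side-chain mutator uses template chi angles; buried mutations can
  clash, which the count-based features tolerate but energy-based analyses
  would not.
* SASA rotation invariance is statistical (sampling), not exact.
* The 83-feature selection reported for the original antibody study is a
  data-dependent outcome, not a property of this implementation; greedy
  selection here returns whatever the data support.
* mmCIF input, protonation, rotamer optimization and energy minimization are
  out of scope by design.
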