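# Methods

This note documents the models implemented in `funcshift`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical conventions. It states no empirical result
beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Contact graphs and microenvironments

A structure (PDB format, parsed with gemmi) becomes an undirected simple
graph whose vertices are the standard amino acid residues, identified by
chain and author residue number with any insertion code concatenated.
Two contact rules are provided:

* `any_atom`, threshold **4.5 Å** (default): an edge when the closest
  pair of atoms of two residues is within the threshold;
* `c_alpha`, threshold **6.0 Å**: Cα–Cα distance.

The any-atom rule is the default because it is the construction the
predictors are defined on; the Cα rule matches the convention often used
for rendering contact maps and is kept as a configurable alternative.
Neither is privileged beyond the default — both are exposed in the
configuration.

Alternate locations are resolved to the highest-occupancy conformer
(ties broken by altloc identifier) before any distance is computed.
Non-standard polymer residues are dropped with a logged warning;
HETATM records are retained so metal ions and ligands stay available.

A residue's microenvironment is the induced subgraph on all vertices
within `level` hops of the residue (default **3**; the pipeline demo uses
2 to keep toy environments small). `level = ∞` recovers the connected
component.

**Metal-site labels from geometry.** A residue is labeled as binding
metal M when at least one of its heavy N, O or S atoms lies within
**3 Å** of an M ion. Carbon is deliberately excluded: carbon contacts at
coordination distance are packing, not coordination chemistry. The label
is invariant to atom order and rigid-body motion (distances only).

**Conservation alphabet.** The 20-letter amino acid alphabet optionally
splits into 40 symbols: uppercase for residues whose conservation score
is at or above the median over the *entire* data collection, lowercase
below it. Ties go to the conserved class so that the attained median is
handled deterministically. Conservation is an input (any per-residue
scalar, e.g. relative entropy from an alignment the user supplies); the
package does not compute alignments.

**Variant mapping.** A 51-residue window centred on the variant position
(clamped, not padded, at the termini — exact-substring semantics remain
well defined) is searched for as an exact substring in the
atom-record-derived sequences of structures passing the quality filters
(X-ray, > 50 residues, resolution < 2.5 Å). Only 100%-identity matches
qualify; among multiple hits the lowest resolution wins, with
lexicographic structure id as a deterministic tie-break. Unmapped
variants are flagged with a reason and never dropped silently.

## Graphlet kernels

A graphlet is a simple, connected, rooted, vertex-labeled graph of at
most five vertices. Canonicalization fixes the root at position 0 and
minimises over the (n−1)! remaining orderings — exhaustive but exact,
and cheap at ≤ 4! permutations. Counting enumerates every connected
induced root-containing subgraph exactly once using an
extension/forbidden-set recursion; the test suite checks it against
brute-force subset enumeration on graphs up to 12 vertices.

Edit smoothing adds pseudo-counts: ψ(g) sums raw counts over the edit
neighborhood E(g, m) with unit weights. Supported operations are vertex
label substitution and edge insertion/deletion; vertex
insertion/deletion is defined **atomically on leaves** (a leaf plus its
single incident edge count as one operation). A bare vertex insertion
could never produce a connected graphlet, so under the searched budget
m ∈ {0, 1} cross-size neighbors would otherwise not exist at all; the
leaf convention makes the full-operation mode meaningfully richer than
its label-substitution and edge-indel restrictions, which is the
intended design. Every single operation is invertible inside the size
budget, so neighborhoods are symmetric and smoothing can scatter each
observed count over its own neighborhood (tested explicitly).
Edge-label substitutions are vacuous — the graphs carry no edge labels —
and are accepted as no-ops. Vertex insertion may carry **any** label of
the alphabet, not only labels present in the data; neighborhoods then
depend only on the kernel spec and are cached per
(center, m, mode, Σ, N).

The kernel is the inner product of smoothed count vectors, implicitly
summed over graphlet sizes 1..N, normalized by √(k(u,u)k(v,v)) with
0/0 := 0. Because ψ is an explicit feature map, every Gram matrix is
positive semidefinite by construction. Profiles are sparse maps keyed by
canonical id — the full index space over 40 labels is astronomically
large, and the formulas are index-free under sparsity. Matrices are
assembled through a sparse feature stack rather than pairwise dictionary
dots.

Grid defaults mirror the searched space: |Σ| ∈ {20, 40}, m ∈ {0, 1},
N ∈ {4, 5}, all three operation modes; ties in cross-validated AUC break
toward smaller (N, m, |Σ|) for parsimony.

## Positive–unlabeled training

All predictors are trained from positives plus an unlabeled sample
(default unlabeled size 10 000 in training-set assembly, restricted for
PTMs to modifiable residues — Asn for N-linked glycosylation, Ser/Thr/Tyr
for phosphorylation — and always excluding known positives). The
non-traditional classifier is an SVM on the precomputed normalized
kernel (scikit-learn SVC, capacity C = 1.0, the conventional default;
the underlying solver is deterministic for fixed inputs). A visibly
non-PSD matrix is rejected with a suggestion to add diagonal jitter.

Platt calibration fits P(l=+1|s) = 1/(1+exp(As+B)) by regularized
maximum likelihood with the standard smoothed targets
t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2), using the robust Newton iteration
with backtracking. Calibration on out-of-fold scores is preferred when
they exist; otherwise training scores are used, with the optimism this
implies.

Conversion to a traditional posterior multiplies the calibrated odds by
α·(n/m) and **clips to [0, 1]**: the conversion formula is unbounded,
but the downstream calculus requires proper probabilities; p_l → 1 maps
to 1. The class prior enters either as a user-supplied value (`given` —
priors estimated by external mixture-proportion algorithms belong here)
or through a mean-posterior baseline (`elkan_noto_e1`):
α̂ = mean_unlabeled(p_l)/mean_labeled(p_l), clipped to [0, 1]. The
baseline assumes the supplied scores are *calibrated* labeledness
posteriors; fed raw component scores it inherits their overlap as upward
bias. Prior estimation beyond this baseline is deliberately out of
scope; the interface is pluggable.

Stability labels follow |ΔΔG| > 0.5 kcal/mol (strict inequality; both
stabilizing and destabilizing changes count). The 33 stability mutation
features are a ±1 indicator block over the 20 amino acids plus 13
mutant-minus-wild-type property differences. The identities of the 13
properties are not fully specified by the provenance of the feature set,
so the shipped table (Kyte–Doolittle hydropathy, van der Waals volume,
Grantham polarity, net charge, isoelectric point, flexibility,
accessible surface area, molecular weight, helix and sheet propensities,
side-chain H-bond donors/acceptors, aromaticity) is a documented
reconstruction and is user-replaceable; the feature layout, not the
specific scalars, is the contract (antisymmetry under wt↔mt swap is
tested for any table).

## Evaluation

Cross-validation is per protein chain, 10-fold by default: all residues
of a chain share a fold, fold sizes differ by at most one, assignment is
deterministic per seed. Test-fold items contribute no rows or columns to
training-fold kernels. AUC is the tie-averaged rank statistic; the
operating point is the smallest observed score at which specificity over
the unlabeled-as-negative side reaches 99%, computed on **pooled**
out-of-fold scores (per-fold thresholds would be noisier at the data
sizes involved; pooling is this package's choice where the convention is
ambiguous). Treating unlabeled residues as negatives biases specificity
optimistically — some "negatives" are true sites — and this caveat
applies to every reported operating point. MCC uses the four-count
formula with a zero denominator guarded to 0.

## Mechanism calculus

The loss/gain formulas and their approximations are given in the README.
Numerical conventions: inputs are validated into [0, 1]; complement
products 1 − Π(1 − v) are evaluated in log1p space whenever any factor
exceeds 0.999 to avoid cancellation; the mutant environment is the
wild-type graph with only the root's label replaced (asserted
structurally in tests), and the mutant root **inherits the wild-type
conservation class** — nothing in the training data says how
conservation transfers under mutation, so the class is held fixed rather
than guessed. PTM residue restrictions act on the posteriors directly: a
wild-type residue that cannot carry the modification has p_wt = 0
exactly (no loss), a mutant that cannot has p_mt = 0 exactly (no gain),
each tagged with a reason. The stability mixture is dichotomized into
exactly two strata; a continuous ΔΔG treatment would replace the sum
with an integral and is out of scope. P(S|x) is an explicit input
everywhere a variant is scored, so a trained stability model and a fixed
scalar are interchangeable.

Combined models run over the full function set and per category (metal,
PTM, catalytic, macromolecular, ligand, allosteric) with the same two
combination rules; max ≤ independence always, with equality iff at most
one entry is nonzero.

## Enrichment statistics

The empirical null is the score distribution on putatively neutral
variants (unlabeled minus known-disease overlap). The threshold at FPR q
is the ⌈(1−q)·n⌉-th order statistic; exceedance is **strictly greater**
("greater than a threshold"), so ties at the threshold do not exceed and
the null's own exceedance is ≤ q, with equality exactly when n·q is
integral and the null is tie-free. Enrichment uses the one-tailed
(greater) Fisher exact test on
[[disease_exceed, rest], [neutral_exceed, rest]]; Bonferroni families
default to 2 × (number of single function types) — 58 for the full
29-type registry, jointly over loss and gain, separately per posterior
column — and 4 for the combined independence/max models. Family sizes
are configurable because the correction family is a reporting choice.
Single-variant empirical p-values use the add-one convention
(1 + #{null ≥ s})/(1 + n) to avoid zero p-values.

## Synthetic generators

Every generator is a pure function of (parameters, seed) and writes the
formats the pipeline reads; parameters are serialized alongside outputs.

* **Structures** are self-avoiding lattice walks (3.8 Å steps) with
  small fixed backbone offsets and a pseudo side chain. Geometry is
  deliberately unphysical — no torsions, no sterics beyond
  self-avoidance — because every downstream rule consumes only
  inter-atomic distances. Planted metal sites place the ion so that
  exactly k residues have a coordinating N/O/S atom at 2.0–2.9 Å while
  every other N/O/S atom stays beyond 3.5 Å; generation verifies the
  realised geometry and retries, so geometric labeling recovers the
  planted site exactly by construction.
* **PU score mixtures** use Beta components bounded to [0, 1] like
  calibrated posteriors: background Beta(1, 9), positive Beta(9, 1).
  The generator emits both the raw component draws (for
  mixture-identity checks) and the exact labeledness posteriors
  P(l=+1|score) computed from the known densities with label fraction
  m/(m+n) — the calibrated quantity the prior estimator is specified to
  consume.
* **Planted-motif graphs** embed a rooted labeled motif as an induced
  subgraph at the root of positives (noise adds edges only outside the
  motif block, so the induced motif survives); negatives are
  size-matched random rooted graphs with the same root label, verified
  motif-free by exact counting.
* **Cohorts** mix a high tail (Beta(20, 1)) into a base distribution
  (Beta(1, 19)) with probability equal to the effect size, which
  therefore approximates the extra exceedance mass above any high null
  quantile.

What passing tests on these fixtures shows — and does not show: they
validate the algebra, the algorithms and the end-to-end plumbing under
known ground truth. They do not establish predictive accuracy on real
structures, where environments are larger and denser, conservation is
informative rather than random, functional sites cluster in pockets and
interfaces the generators do not model, and unlabeled sets contain true
positives at unknown rates.

## Problem sizes and defaults in the checked runs

The test suite runs the planted-motif benchmark at 400 environments
(200/200 split) with the N = 4, m = 1, full-operation kernel over the
20-letter alphabet; prior recovery at n = 5000 for α ∈ {0.1, 0.3, 0.5};
exhaustive graphlet oracles on graphs of 8–12 vertices; Fisher
enumeration on all tables of total ≤ 20; and the pipeline demo on three
60-residue structures. These sizes were chosen as the smallest at which
each property is meaningfully exercised.

## Known limitations

* Unlabeled-as-negative evaluation inflates specificity and AUC to an
  unknown degree; reported operating points are optimistic.
* The mean-posterior prior baseline is an upper-bound-flavoured
  estimator; identifiability of class priors from PU data is limited in
  principle, and externally estimated priors can be supplied instead.
* Graphlet kernels see topology and labels only; solvent accessibility,
  pockets and electrostatics are invisible, which particularly limits
  macromolecular-interface functions.
* The stability stratum is binary; borderline ΔΔG effects are forced
  into one of two regimes.
* mmCIF support is whatever the parser provides; NMR/EM structures are
  excluded by the quality filters, and homology modelling is out of
  scope.
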