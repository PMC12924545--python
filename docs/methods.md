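# Methods

This note documents the models and procedures implemented in `protacut`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## Attachment-point conventions

Fragments are exchanged as SMILES with map-numbered dummy atoms: `[*:1]` on
the warhead-facing side of a junction, `[*:2]` on the E3-facing side. A
warhead carries exactly one `[*:1]`, an E3 ligand exactly one `[*:2]`, and a
linker one of each. The bond drawn between a dummy and its real neighbor
records the junction bond order; `reassemble` requires the orders to agree
pairwise across each junction and fails otherwise. Canonical forms are
RDKit's default canonical SMILES with stereochemistry retained; all
exact-match comparisons use this form. `strip_stereo` produces the
stereo-free variant used for the dictionary copies.

A *bridge bond* is any bond outside every ring (SSSR membership test); for
a connected molecule its removal disconnects the graph. Cutting two distinct
bridge bonds always yields exactly three fragments whose component graph is
a path, so the middle fragment — the only one incident to both cuts — is the
linker. Heavy-atom counts exclude dummies, so cuts conserve heavy atoms
exactly: `heavy(parent) = heavy(warhead) + heavy(linker) + heavy(e3)`.

## Dictionary-based annotation

Substructure matching is *attachment-consistent*: the tag-stripped ligand is
embedded in the parent such that each attachment atom has exactly one bond
to an atom outside the match (the junction, whose order must equal the
ligand's dummy-bond order) and no other matched atom has any external bond.
Embeddings are enumerated without RDKit's `uniquify` option: for symmetric
ligands the automorphic embeddings differ in which atom faces the junction,
and only some orientations pass the consistency filter; matches are instead
deduplicated on (atom set, junction bonds).

The cascade:

1. **Both ligands matched.** Warheads and E3 ligands are tried largest-first
   (heavy atoms descending, lexicographic SMILES tie-break); the first
   atom-disjoint pair with distinct junction bonds that yields a
   reassembly-valid cut wins. Largest-first avoids trivial small-fragment
   matches; enumerating warheads in the outer loop makes the choice
   deterministic and biases toward the largest matched content (the exact
   maximization of warhead+E3 heavy atoms over all pairs is not performed —
   first-wins under this ordering is a close, cheaper proxy).
2. **One ligand + linker.** If stage 1 fails but at least one terminal
   ligand matched, linkers are tried largest-first for an embedding that is
   disjoint from the ligand match and whose junction on the known-ligand
   side coincides with that ligand's junction bond (junction consistency).
   The remainder becomes the missing ligand.
3. **Linker only.** Linkers largest-first; the two leftover fragments are
   assigned warhead vs E3 by their maximum Tanimoto similarity (512-bit
   Morgan, radius 2, on tag-stripped structures) to the warhead and E3
   dictionaries; ties break toward the fragment with higher E3 similarity,
   then toward the tag-2 end.

Every annotation is validated by exact reassembly against the canonical
parent; failures carry the deepest stage reached and feed a manual queue.

**Attachment-point refinement.** Cuts chemists would not draw — one bond
away from an amide or ester — are shifted onto the acyl C–N (amide) or
C–O (ester) bond. "Within one bond" is operationalized as: the junction bond
shares an atom with the acyl C–X bond, or one of its atoms neighbors the
carbonyl carbon; this is the smallest reading that covers both sides of the
group. Only non-ring acyl bonds qualify (lactams/lactones are never cut);
the carbonyl stays with the fragment that contained it, roles are reassigned
by atom overlap with the pre-refinement fragments, and the refined cut is
re-validated by reassembly — if anything fails the unrefined annotation is
returned with a warning. The operation is idempotent because a junction
already sitting on an acyl bond is left alone.

**Iterative refinement** over a corpus repeats full-corpus annotation,
inserting newly inferred warheads, linkers and E3 ligands into their
dictionaries after each molecule, until a round annotates nothing new and
inserts nothing new. Termination is guaranteed in at most corpus-size + 1
rounds: each earlier round makes progress and dictionary growth is bounded
by the corpus's substructure content.

## Synthetic library generation

Connection types — (bond order, ordered element pair of the joined atoms) —
are modeled as a categorical distribution per junction, estimated
empirically from an annotated corpus or configured directly. Generation is
category-first: a type is drawn independently for each junction, then a
warhead / linker / E3 triple is drawn uniformly among ligands whose
attachment element and dummy-bond order are compatible. Category-first
sampling enforces the junction-type marginals directly; the two junctions
are treated as independent. Within each category cell, triples are drawn
uniformly *without replacement* from a seed-shuffled deck: duplicate parents
are rejected and retried within the same cell, so the emitted category
counts stay multinomial under the configured distribution instead of
drifting toward large cells (with plain independent resampling the drift
exceeds 3 standard errors already at 10,000 molecules). Categories with no
compatible ligands are logged and renormalized away; if the retry budget is
exhausted a partial library is returned with a warning. Uniqueness is
enforced on stereo-retained canonical parent SMILES, and every stored
annotation is produced by the reassembly call itself, so it round-trips
exactly by construction.

**Cluster splits.** Ligands are clustered per role with Taylor–Butina
sphere exclusion on 1,024-bit Morgan fingerprints (radius 16, chirality
encoded) at a default Tanimoto-distance cutoff of 0.4. The high radius is
the splitting protocol's setting and is far above customary values (2–3);
`FingerprintSpec` makes it configurable for sanity comparisons. Randomly
selected clusters are reserved until a holdout fraction (default 0.2) of
each role's ligands is covered, keeping at least one cluster in train; every
molecule containing a reserved ligand is excluded from train and assigned
alternately to validation/test. The unseen report counts held-out molecules
with 1, 2, or 3 components absent from the train ligand pool. A degenerate
single-cluster situation in every role raises a split error advising a
different cutoff.

## Graph splitter

Bond features, computed for bridge bonds only (ring cuts are never
meaningful here):

* normalized betweenness centrality of the bond's node in the molecular
  line graph (standard combinatorial normalization; a per-molecule min-max
  rescale is available via `SplitterConfig.per_molecule_scale`);
* counts of nodes at shortest-path distance exactly 1, 2 and 3 from each
  endpoint atom in the hydrogen-suppressed molecular graph, stored
  orientation-invariantly as (max, min) per order, and the same three
  orders for the bond's node in the line graph;
* bond order and the lexicographically sorted endpoint element pair
  (one-hot encoded, unknown categories ignored at predict time);
* a 512-bit Morgan fingerprint (radius 6) of the whole molecule, shared by
  all of the molecule's bond records and reduced to 50 dimensions by
  truncated SVD.

Labels come from annotated molecules: the two junction bonds are positive,
every other bridge bond negative — exactly two positives per molecule
against tens of negatives. The training pipeline therefore oversamples the
minority class to 1:1 with SMOTE (k = 5 nearest minority neighbors, uniform
interpolation; implemented in-package on top of scikit-learn's
NearestNeighbors) before fitting an XGBoost classifier with library-default
hyperparameters and a fixed seed — no hyperparameter search. SMOTE touches
the training fold only; scoring never resamples.

At prediction time all bridge bonds are scored, the top two are cut (ties
broken by score, then betweenness, then bond index), the middle fragment is
the linker, and the end fragment with the higher *average* Tanimoto
similarity (512-bit Morgan radius 2, tag-stripped) to the E3 reference set
is the E3 ligand. The reference set holds min(50, n) training E3 ligands:
k-means centroids over fingerprints, each represented by its nearest actual
member. Attachment-point refinement is applied last. Because the output is
a two-bond graph cut of the input, every prediction parses, reassembles
exactly, and conserves heavy atoms — validity 100%, reassembly 100%, extra
atoms 0, on any input the model can split at all; molecules with fewer than
two bridge bonds raise an explicit error rather than a malformed triple.

## Prediction fixer and hybrid strategy

Sequence models hallucinate — an extra "C" in a long alkyl chain — but the
parent is known and any two correct components determine the third. If the
predicted triple already reassembles it is returned untouched. Otherwise
every pair of parseable components is tested for disjoint
attachment-consistent embeddings (with shared junctions required to
coincide); the winning pair's junctions are cut and the third component is
thereby replaced. Candidate pairs are ranked by pair class first —
(warhead, E3) over (warhead, linker) over (linker, E3) — then by largest
joint heavy-atom count, then deterministically. The class ranking exists
because the failure mode it guards against is real: a chain linker that
lost one atom still embeds shifted by one position, and a preference purely
on joint size would select that shifted pair and "repair" the intact
warhead instead; the two terminal ligands anchor both junctions
independently and are ring-anchored, so wrong terminal predictions rarely
embed at all. Errors spanning both linker attachment points are not
special-cased and fall through to `unfixable`.

The hybrid strategy wraps any external prediction: accept it if it is valid
or fixable, otherwise fall back to the graph splitter. Since the fallback
reassembles by construction, hybrid reassembly is 100% on any corpus.

## Evaluation metrics

* **Validity** — all three SMILES parse (per-component rates in the
  per-role block).
* **Exact match** — all three canonicalized components string-equal to the
  labels, attachment tags included; per-role rates are computed
  independently, so the global rate is at most each per-role rate.
* **Reassembly** — the joined, canonicalized triple reproduces the parent
  exactly. An exact match always reassembles, so exact ≤ reassembly; a
  valid triple need not reassemble.
* **Extra atoms** — `heavy(parent) − heavy(prediction)`, computed only over
  predictions failing reassembly (positive = missing atoms, negative =
  hallucinated). For a non-reassembling triple the prediction's heavy-atom
  count is the sum over its parseable components; per-role means compare
  each predicted component against its label.

Components are canonicalized before comparison, so all metrics are
invariant to the formatting of the input SMILES. The centrality baseline —
cut the two highest-betweenness bridge bonds subject to both end fragments
keeping ≥ 5 heavy atoms, fall back to the top pair — is a simple heuristic
native to this package, provided as a learning-free reference point.

## Toy fixtures and what they do (and do not) show

Toy ligands are enumerated from hand-written SMILES templates with
combinatorial decorations, never random graph edits, so every emitted
structure is chemically valid. Warheads are decorated (hetero)aromatics,
linkers are alkyl/polyether chains of 2–15 heavy atoms, E3 ligands are
acyl-bearing saturated rings of 6–20 heavy atoms — the roles are separable
in fingerprint space by design, so Tanimoto role assignment is learnable.
Two further properties are deliberate:

* every warhead and E3 attachment point is a **ring atom**, so a
  dictionary fragment can never absorb acyclic linker atoms across a
  junction and each generated molecule decomposes uniquely under its source
  dictionaries (this is what makes annotation an exact oracle on the toys);
* every carbonyl sits at least two bonds from an attachment point, so
  ground-truth junctions are fixed points of attachment refinement.

The default junction-type mix (70/30 single C–C vs C–N at the warhead
junction, 60/40 single C–C vs C–N at the E3 junction) mirrors the dominance
of alkyl and amine couplings in degrader chemistry.

Real PROTACs are harder in every way the toys are easy: components share
motifs across roles, decompositions can be ambiguous, junctions are not
marked by a single local pattern, and macrocycles defeat bridge-bond cutting
entirely. Passing the toy suites therefore demonstrates the *structural
guarantees* (validity, reassembly, atom conservation, recovery under
corruption) and the correctness of the machinery, not real-world exact-match
accuracy — on real corpora the graph splitter's exact-match is far below
100% even though its structural guarantees still hold identically.

`corrupt_component` applies exactly one edit to one component — methylene
insertion into an acyclic C–C bond, chain-atom deletion with neighbor
rejoining, or string invalidation — and errors out when the edit is
inapplicable (e.g. deleting from a single-atom fragment).

## Problem sizes and numerical choices

The bundled study conditions use dictionaries of 32 warheads, 48 linkers
and 32 E3 ligands (seed 7), a 2,500-molecule library (seed 42) split 2,000
train / 500 held-out, 10,000 molecules for distribution-fidelity checks,
500 corruptions for fixer recovery, and 200 half-corrupted molecules for
the hybrid guarantee. These sizes exercise every code path at full fidelity
while keeping the complete suite and the acceptance script fast on a single
CPU. Distribution fidelity is asserted within 3 binomial standard errors
per category; probability normalization within 1e-9; all random draws flow
from explicit seeds (Python `random.Random`, NumPy `default_rng`, and the
`random_state` of scikit-learn/XGBoost components), making generation and
training bit-reproducible.

## Known limitations

* Canonical-SMILES exact matching is toolkit-specific; a different
  cheminformatics toolkit would produce different canonical strings, so
  cross-toolkit exact-match rates can differ on edge cases.
* The splitter cannot handle molecules with fewer than two bridge bonds
  (e.g. fully macrocyclic degraders) and misidentifies cut sites on
  topologies whose junctions carry no local signal.
* The fixer repairs exactly one wrong component; simultaneous errors in two
  or three components are out of scope.
* Nothing distinguishes non-PROTAC inputs: any molecule with two bridge
  bonds will be split into three parts.
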