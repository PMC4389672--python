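# Methods

## Model

Let a protein's domain signature (DS) be the set of distinct Pfam-A family
accessions assigned to it. Training uses single-EC enzymes that carry a DS;
multi-EC proteins, EC-less proteins and enzymes without Pfam-A domains are
excluded (tallies are logged). For each EC hierarchy level k ∈ {1,2,3,4} the
trainer groups proteins by DS, splits each group into subgroups by the first
k EC digits, and records every subgroup's count. The specificity of a DS–EC
pair is the subgroup's abundance within its group, N(DS,EC)/N(DS), kept as an
exact `fractions.Fraction`. Enzymes annotated shallower than k contribute
nothing to the level-k model: a depth-2 EC number carries no information
about sub-subclass membership, so treating it as evidence at level 3 would
bias the counts.

Prediction is gated by the specific-enzyme-DS set (enzyme-derived DSs minus
DSs also seen in reliable non-enzymes) and then descends the levels. The
engine is deterministic and contains no randomness.

### Prefix-conditioned descent

Each level model independently stores an *unconditioned* dominant subgroup,
but the per-level dominants of one DS need not form a single EC lineage: with
subgroup counts {1.1: 3, 1.2: 2, 2.1: 4} the level-1 dominant is "1" (5/9)
while the unconditioned level-2 dominant is "2.1" (4/9). The engine therefore
restricts level-k candidates to subgroups extending the digits already
emitted at level k−1, while still measuring specificity as abundance within
the whole DS group. Because each level-(k+1) subgroup is nested in its
level-k parent and all abundances share the group size as denominator, the
confidence sequence is non-increasing — matching the intended reading of the
descent and keeping the output a single EC lineage. The alternative reading
(take the unconditioned dominant, truncate at the first inconsistency with
the emitted prefix) is available via `EngineConfig(conditioned=False)`; on
lineage-consistent groups the two coincide.

### Numerical and tie-break choices

* Specificities are exact rationals end to end, including in the model file
  (integer count + group size per subgroup row). Threshold comparisons at
  printed operating points (0.80, 0.99) are therefore exact; a specificity
  *equal* to the threshold passes (the stop rule fires only strictly below).
* Dominant-subgroup ties are broken toward the smallest EC prefix under a
  numeric-aware token order (2 < 10; numeric tokens before preliminary
  tokens like `n5`). Any deterministic rule would do; smallest-EC is
  reproducible across platforms and releases.
* EC tokens are opaque strings; the algorithm needs only token equality, so
  preliminary identifiers survive unharmed. Rendering is always dash-padded
  to four positions (`1.1.-.-`).
* A DS present in the specific-DS set but missing from the level-1 model
  (possible only with inconsistent model/filter inputs) yields
  UNRESOLVED_ENZYME with a warning rather than an exception.

## Parameters

| parameter | default | meaning |
|---|---|---|
| specificity threshold | 0.80 | stop descent when the DS–EC specificity drops below it; 0.99/0.90/0.70 are the other operating points worth sweeping |
| non-enzyme exclusion terms | 9 built-in terms | case-insensitive substrings (`iron sulfur`, `uncharacterized`, `biosynthesis`, `ferredoxin`, `ase`, `enzyme`, `hypothetic`, `putative`, `predicted`) that disqualify an EC-less protein from the reliable non-enzyme set |
| min sub-subfamily size | 50 | evaluation-time filter dropping enzymes whose level-3 prefix has fewer members (strictly fewer; 50 stays) |
| k (cross-validation) | 10 | folds; uniform random partition by seed, sizes ⌊n/k⌋/⌈n/k⌉ |

The exclusion terms are matched as plain substrings against the concatenated
DE/KW/DR text of the whole entry, so `ase` also removes e.g. "ATP synthase"
and even "base"-containing descriptions. Over-exclusion only shrinks the
reliable non-enzyme corpus, which makes the specific-DS subtraction
conservative (fewer enzyme DSs are discarded); under-inclusion of enzymes in
that corpus is the error the nine terms guard against.

## Evaluation scheme

`classify` is a total function on (PE, TE) pairs of EC-or-Non-enzyme labels:
digit mismatch within the common depth ⇒ OP; identical depth and digits ⇒ E;
correct but shallower ⇒ IA; correct and deeper ⇒ IM; TE Non-enzyme ⇒ E if PE
is too, else OP; PE Non-enzyme against an enzyme truth ⇒ IA. NO_DOMAIN,
NON_ENZYME and UNRESOLVED_ENZYME predictions all count as Non-enzyme here,
since none assigns a digit; the depth distribution in `CVReport` keeps them
separate. Example-based precision/recall decompose each enzyme label into its
four per-level renderings (`1.1.-.-` → {`1`, `1.1`, `1.1.-`, `1.1.-.-`};
Non-enzyme stays a singleton) and average per-protein overlaps, computed in
exact arithmetic before the final float conversion. Truths shallower than
four digits still decompose to four elements (dash-padded), which is the
literal reading of the decomposition rule; IM pairs consequently share only
the annotated-prefix elements.

Cross-validation rebuilds everything per fold — the four level models *and*
the specific-DS set from the fold's training enzymes. The reliable non-enzyme
corpus is held fixed (it is reference material for the subtraction, never
predicted); folding it as well would only shrink the subtrahend and is the
weaker reading. Folds with no trainable enzyme are skipped with a warning.

## Synthetic corpora

The generator emulates what the trainer consumes: DS-sharing protein groups
with exact, user-specified EC compositions, plus a non-enzyme population of
which a chosen fraction reuses enzyme DSs (to exercise the specific-DS
subtraction). Accessions come from the reserved `PFTEST#####` namespace, ids
are sequential, and output is a pure function of the spec (including its
seed). It deliberately does not model: amino-acid sequences or HMM scores
(the pipeline is tested from domain assignments down), partial-depth truth
annotations unless specified, correlations between DS size and EC class, or
the heavy-tailed family-size distribution of real databases. Passing tests
on synthetic corpora therefore demonstrate algorithmic correctness —
counting, gating, thresholding, scoring — not real-database performance, for
which the Pfam/Swiss-Prot inputs themselves would be needed.

`perturb_labels` flips a fraction of enzyme labels to other ECs drawn from
the corpus, emulating annotation error in automatically annotated databases;
the overprediction fraction under cross-validation rises with the flip rate.

Default study conditions used by the test suite and acceptance script: the
worked 100-protein single-DS group (43/42/3/2/10 mixture over five four-digit
ECs, giving per-level dominant fractions 0.90/0.88/0.85/0.43); pure-group
corpora of ten 20-member groups plus four 5-member non-enzyme groups for the
cross-validation properties; random corpora of ≤500 proteins for the
brute-force oracle and monotonicity sweeps. These sizes make every expected
value computable by hand or by exhaustive recount while exercising all code
paths; the pipeline itself streams linearly in corpus size.

## Domain assignment

`run_hmmsearch` executes HMMER in process via pyhmmer with
`bit_cutoffs="trusted"`, the in-process equivalent of
`hmmsearch --cut_tc` with defaults otherwise; any domtblout produced by an
external HMMER run can be supplied instead, in either search direction
(`--query-is-protein` transposes the column mapping). Pfam accession version
suffixes are always stripped before DS construction so signatures survive
Pfam release bumps. All DomainHit sources are treated as equivalent
downstream.

## Known limitations

* Domain architecture cannot fully encode substrate specificity; fourth-digit
  assignments lean entirely on the training mixture of the DS group.
* The enzyme/non-enzyme gate is a hard set-membership test; borderline DSs
  are classified all-or-nothing (a probabilistic gate is out of scope).
* Multi-EC proteins are excluded from training and rejected by the evaluator;
  the tool never predicts more than one EC per protein.
* The simple DS ignores domain recurrence and order by construction; variants
  that keep them are intentionally not implemented.
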