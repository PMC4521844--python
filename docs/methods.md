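# Methods

This note documents the models, detectors and design choices behind
smydkit, and what the synthetic-data tests do and do not demonstrate.

## Homology filtering

Candidates arrive as 12-column tabular BLASTP output; BLAST itself is
external. Three rules decide acceptance:

1. **Similarity** — the subject's best hit (lowest E-value, ties broken by
   bitscore, then subject id) must have E-value strictly below
   `evalue_max` (default `1e-7`).
2. **Continuity** — at least one *single* HSP must cover ≥
   `min_core_coverage` (default 0.9) of the query's SET-MYND core
   interval. Tabular output does not expose within-HSP gap placement, so
   large internal breaks are proxied by the net discrepancy between the
   HSP's query-span and subject-span lengths, which must not exceed
   `max_internal_break` residues (default 10). HSPs are never merged:
   co-linearity through the core is the point of the rule, and merging
   would accept rearranged matches.
3. **Reciprocity** — the candidate's top hit in a reverse search against
   the seed proteome (same best-hit ordering) must itself belong to the
   seed set; candidates with no reverse hits fail with an explicit reason.

Tightening any threshold can only shrink the accepted set; this
monotonicity is asserted by tests over randomized hit tables.

## Core extraction and gap policies

The family alignment is trimmed to the contiguous column block bounded by
two residues of an ungapped reference (human SMYD1 residues 18–279 by
convention; all coordinates in the package are 1-based inclusive). Rows
that are entirely gaps inside the block are kept but flagged.

Three column policies feed the distance stage: *partial deletion* keeps
columns whose non-gap fraction is ≥ the coverage cutoff (default 0.65;
ties at the cutoff are kept, reading "cut-off" as inclusive); *complete
deletion* keeps only gap-free columns; *pairwise deletion* keeps all
columns and uses, per pair, the sites where both sequences are non-gap.
Coverage is computed over all rows including the reference, and any
non-gap character (including X) counts as coverage. Residual gaps inside
globally kept columns are excluded per pair, since no mismatch can be
scored against a gap.

## Distances, neighbor joining, bootstrap

Let `p` be the proportion of differing usable sites (X mismatches
everything, including another X). Available models:

* `p` — observed proportion.
* `poisson` — `d = -ln(1-p)`; errors as "saturated" when `p ≥ 1`.
* `poisson_gamma` — `d = a((1-p)^(-1/a) - 1)` with gamma shape `a`
  (default 5, the study's setting). As `a → ∞` this converges to the
  Poisson correction, and it is ≥ the Poisson correction for every
  `p ∈ (0,1)`; both facts are asserted in tests.
* `jtt_ml` / `jtt_ml_gamma` — one-parameter maximum likelihood under the
  empirical JTT replacement model (Jones–Taylor–Thornton 1992; bundled as
  `data/jtt.json`, exchangeabilities and equilibrium frequencies on the
  standard ARNDCQEGHILKMFPSTWYV order). The generator is normalised to one
  expected substitution per unit time; `P(t) = exp(Qt)` is computed by
  symmetric eigendecomposition and the branch length maximising
  `Σ_ab N_ab log(π_a P_ab(t))` is found by bounded scalar optimisation on
  `t ∈ [1e-8, 50]`. The gamma variant averages `P(r_k t)` over 5
  equal-probability discrete gamma categories with mean category rates.
  Sites containing X are excluded (X is not a JTT state). At small
  divergence the estimate agrees with the p-distance to first order.

Neighbor joining is the standard agglomerative algorithm on the
Q-criterion. Two determinism conventions matter for testing: exact ties in
Q are broken by the lexicographically smallest pair of cluster labels
(a cluster is labelled by its smallest member taxon), and negative branch
lengths are clamped to zero with the deficit moved to the sibling edge
(the raw value is kept on the edge as `raw_length`). On additive matrices
NJ recovers the generating topology and branch lengths exactly; the test
suite checks this on seeded random additive matrices (4–12 taxa) against a
least-squares brute force over all topologies (4–6 taxa) and path-length
additivity.

Bootstrap support resamples alignment columns with replacement (seeded
NumPy generator), rebuilds the NJ tree per replicate, and annotates each
internal edge of the point-estimate tree with the percentage of replicates
containing the same bipartition. Support is displayed on the point
estimate, not a consensus. Supports are stored both as numeric node
attributes and as internal-node labels in Newick output (the dominant
dialect for bootstrap trees).

## MYND Zn-finger model

A cross-brace MYND-like finger is modelled as eight ligand positions in
four pairs; pairs 1 and 3 coordinate the first Zn ion, pairs 2 and 4 the
second. The signature lives in a versioned data file
(`data/mynd_zn_pattern_synthetic.json`): allowed residues per ligand slot
(Cys everywhere, His tolerated at slot 7), within-pair spacer bounds
(short and near-invariant) and between-pair spacer bounds (longer and
variable, pair 1–2 the most). The file is a constructed stand-in — built
from the qualitative cross-brace description, not copied from a database
release — and is the single source of truth: the detector, the synthetic
generator and the tests all read the same bounds, so the framework is
internally consistent and the file can be swapped for a database-derived
pattern without code changes.

The search enumerates, by backtracking over candidate ligand positions,
*every* octet satisfying a relaxed version of the signature, then scores
each octet by its deviations from the unrelaxed signature
(`spacing_long`, `spacing_short`, `ligand_substitution`, `missing_pair`);
the score is the unweighted deviation count. Relaxation defaults:
between-pair spacers may overshoot by up to 100 residues (so a finger with
an ~84-residue pair 1–2 spacer is still findable), within-pair spacers by
only 4 (within-pair spacing is the invariant part of the cross-brace
geometry, and a tight bound keeps the search linear in practice); all
spacers may undershoot by 3; His↔Cys swaps are tolerated; Glu as a ligand
only behind an explicit flag. On sequences with few candidate ligands the
enumeration is proven equivalent to exhaustive brute force over all
octets.

Categories: **canonical** (no deviations), **partial_left** /
**partial_right** (the pairs-1–2 or pairs-3–4 portion deviation-free while
the other is not; the pair 2–3 spacer belongs to neither portion — a hit
whose only deviation is a long pair 1–2 spacer is partial_right),
**half** (four ligands interpretable as pairs 1 and 3, binding a single
Zn ion; searched only when no full finger exists), **atypical** (anything
else). Secondary-structure evidence, when supplied, marks a finger
*supported* if a β-strand run immediately precedes pair 3 and a helix run
overlaps the pair-3-to-pair-4 span.

## Architectures and classification

The acidic-tract detector returns the longest window ending at the C
terminus with E+D+S fraction ≥ 0.6 over ≥ 10 residues; the composition
class is E if glutamate alone reaches the threshold, ED if Glu+Asp do,
EDS otherwise. The thresholds are free parameters (no quantitative
definition of a "tract" exists to our knowledge); they accept poly-E tails
and E/D/S mixtures while rejecting typical C termini, and are exposed in
the API. Detection is anchored at the C terminus, hence invariant to
prepending sequence.

Architectures merge core spans (from external annotations or the
generator), the best core finger, extra fingers outside the core
(`MYND_EXTRA`), the acidic tract, and external TPR_N/CTD annotations into
an N-to-C signature; the four core components collapse into one token
(`S/ET+M` canonical finger, `S/ET+m` degenerate, `S/ET` none). Class
candidates are a pure function of the signature:

| signature pattern | candidates |
|---|---|
| TPR_N + core + CTD | SMYD4 |
| core + CTD (no TPR_N) | SMYD3 |
| core + acidic (no CTD/TPR_N) | SMYD5 |
| TPR_N + core + C-terminal extra MYND | ATYPICAL_TPR |
| bare core with degenerate finger | SMYDA |
| anything else | ∅ (defer to the tree) |

The CTD (a TPR-fold domain) is accepted only from external annotations or
generator truth — the bundled TPR heuristic is not reliable for it — and
its absence is never used as evidence against SMYD3/SMYD4 when no
external annotations were provided.

Classification walks the bootstrapped tree: for each query, the smallest
clade induced by an internal edge with support ≥ `min_support` (default
70; the underlying study uses bootstrap support qualitatively, so the
cutoff is a package choice) that contains the query and at least one
anchor, with all contained anchors of one class, yields the tentative
class. Both sides of every supported edge count as clades (unrooted
semantics). A non-empty architecture candidate set must contain the
tentative class, otherwise the call is demoted to UNCLASSIFIED with a
disagreement flag — architecture confirms but never overrides the tree.
Queries with no qualifying clade but a unique architecture class receive
it as architecture-only evidence. Subgroups (Smyd4/Smyd4L/Smyd4I,
Smyd1/2/3) reuse the same rule with subgroup-labelled anchors. Raising
`min_support` can only move calls toward UNCLASSIFIED. `suggest_ortholog`
returns the anchor at minimal patristic distance, ties broken by the
higher minimum support along the connecting path.

The default anchor file ships the five human SMYDs and the *Drosophila
melanogaster* catalog with class/subgroup labels; two of the fly subgroup
identities are inferences (flagged in the file) and user-overridable.

## Synthetic families

The generator emulates the study's data shape without any downloads. One
family = a caterpillar backbone over class roots (classes are ancient,
well-separated splits; backbone plus class subtrees each take half the
configured root-to-tip divergence) with a Yule subtree per class
(birth rate 1.0, branch lengths scaled to the target depth, minimum
branch 0.02 substitutions/site so short internal edges remain resolvable);
Smyd4 subgroups, when configured, form nested clades within the Smyd4
subtree.

Default study conditions: 4 sequences per class (20 taxa), root-to-tip
divergence 0.3 substitutions/site, 300-residue cores for unit tests and
2,000-residue cores for end-to-end recovery runs, uniform 20-state
substitution (a JTT mode is available), and one degenerate-finger schedule
for SmydA (a His-for-Cys substitution at the first pair-2 ligand and a
pair 1–2 spacer stretched 6 beyond its bound — yielding category
partial_right, matching the "right portion intact" pattern typical of
divergent fingers).

Sequences evolve by independent-site substitution with **no indels**, so
the emitted core alignment is the true, gap-free alignment and no aligner
is needed; an indel process is out of scope (consequence: alignment-error
robustness is *not* tested by this package). Planted diagnostic features
— finger blocks, TPR repeats, the acidic tract — are masked invariant by
default (`mask_features=False` lets them decay). The core evolves along
the *whole* tree; each class root splices in its class-specific finger
block and applies an extra `template_divergence` (default 0.1
substitutions/site) of core substitutions, so class templates differ even
at divergence 0. Because these template edits happen at the class root
they act like a longer root edge and remain tree-additive. Flanks evolve
within each class subtree from class-specific templates.

Background composition is drawn from JTT equilibrium frequencies with Cys
and His zeroed out (ligand candidates occur only where planted, plus
whatever drift introduces — mirroring the rarity of those residues and
keeping the finger search well-posed); flank and linker segments
additionally exclude E/D/S so that acidic tracts exist only where planted
and the truth labels are unambiguous by construction. The acidic-tract
truth token is computed by running the detector on the class template,
since the detector's longest-window rule may legitimately extend past the
planted block.

What passing tests show: the pipeline's stages are correct and mutually
consistent on data matching its assumptions (true alignment, external
domain annotations, masked diagnostic sites, site-independent evolution).
What they do not show: robustness to alignment error, indels, compositional
heterogeneity, annotation noise, or divergence high enough to saturate
distances.

## Numerical and engineering choices

* All randomness flows through seeded NumPy generators (tree simulation
  seeds derive from the family seed); identical configuration gives
  byte-identical outputs.
* Distance matrices must be symmetric, non-negative, zero-diagonal;
  triangle violations are permitted (distances are estimates).
* Bootstrap on a 60-taxon, 260-column alignment with 500 replicates runs
  in well under a minute with the closed-form distances; the JTT ML
  distance is scalar-optimised per pair and is the slow option, intended
  for point estimates rather than deep bootstraps.
* End-to-end recovery runs use 20 taxa × 2,000 core sites × 20 seeds with
  100 bootstrap replicates — sizes chosen so the whole suite runs
  comfortably on a laptop while keeping every internal edge statistically
  resolvable.
* Degenerate inputs: empty FASTA → empty list; fewer than 3 taxa → NJ
  error; saturated pairs and zero shared sites abort the distance matrix
  naming the offending pair; an all-gap row inside the extracted core is
  flagged, not dropped.

## Known limitations

* The Zn-finger signature file is a constructed stand-in (see above), not
  a database release; absolute finger calls on real proteomes should swap
  in a curated pattern.
* The TPR heuristic is a single-profile matcher tuned for the generator's
  repeats; real TPR detection should come from external annotations.
* No maximum-likelihood tree search, rooting, or divergence dating; the
  tree stage is distance/NJ only.
* The homology filter consumes tabular BLAST output only; it cannot see
  within-HSP gap structure and approximates "continuous alignment" as
  described above.
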