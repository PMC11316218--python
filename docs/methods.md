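# Methods

## Problem and approach

Type III polyketide synthases (PKSs) form a homodimeric enzyme family
(chalcone synthase and relatives) defined by a Cys–His–Asn catalytic
triad. Within the family, two subfamilies carry well-characterised
diagnostic residues: ASCL (anther-specific chalcone synthase-like,
required for sporopollenin precursor synthesis) and ORS
(2′-oxoalkylresorcinol synthase, a bryophyte/charophyte subfamily).
`pks3` implements the standard survey procedure: validate candidacy by
the triad plus the (G/A)FGPG signature, call the subfamily from
diagnostic residues under reference-based numbering, and corroborate the
call by clade placement in a bootstrapped distance tree.

## Candidacy and classification

A query is aligned globally (Needleman–Wunsch via biopython's
`PairwiseAligner`) to every reference profile; scoring defaults to
BLOSUM62 with affine gaps (open 11, extend 1 per additional residue),
overridable through `ScoringConfig`. The best-scoring profile supplies
the alignment used for the triad check. Each class's diagnostic residues
are always evaluated through the alignment to *that class's own
reference*, because the diagnostic coordinates are defined on that
reference's numbering (Gly225, (Ala/Val)240 for ASCL; Gln218,
(Val/Ala)277, Ala286 for ORS).

Label logic:

* `not_PKSIII` — triad incomplete, signature absent, or no alignment
  scoring above a configurable floor (`min_alignment_score`, default 0);
* `ASCL` / `ORS` — candidacy holds and exactly one full diagnostic set is
  satisfied;
* `ambiguous` — both full sets satisfied (never observed in practice; the
  sets occupy disjoint positions, so this requires an engineered input);
* `other_PKSIII` — candidacy holds, neither set complete.

A reference position aligned to a gap, or an `X` in the query, never
satisfies a requirement. The signature scanner accepts matches anywhere
in the sequence; restricting it to the canonical C-terminal location
would require committing to a reference-mapped window, and presence
anywhere is the more conservative candidacy test.

Fusion proteins (flagged in the input, or longer than 1.8× the longest
reference) are reduced to the segment covered by the best local
alignment to a reference, padded by 20 residues each side and clipped to
the sequence; extraction fails loudly (`NoDomainError`) below a local
score floor of 100, which on BLOSUM62 corresponds to a short but
unmistakable homologous core.

## Multiple alignment

The built-in aligner is progressive: fractional k-mer distances (k = 3,
distinct-k-mer sets, 1 − shared/min) feed a neighbor-joining guide tree,
and profiles are merged bottom-up with a profile–profile Gotoh algorithm
whose column score is the mean BLOSUM62 score over non-gap residue pairs.
Ties in the dynamic program are broken in a fixed state order, so output
is deterministic. This is intentionally simpler than MUSCLE (no
iterative refinement); for publication-grade work an external alignment
can be imported (`import_alignment`) and flows through the identical
downstream stages. Columns are never filtered by default.

## Distances, trees, support

Pairwise distances are maximum-likelihood estimates under the JTT model
(published exchangeabilities and equilibrium frequencies; equal rates
across sites). For each pair, columns containing a gap or `X` in either
row are dropped (pairwise deletion); the likelihood
∑ log(π_i P_ij(t)) is maximised over t by bounded scalar optimisation
(tolerance 1e-8). Estimates at the saturation cap (10 substitutions/site)
are flagged; the run aborts only if a pair has no shared gap-free column.
P(t) is computed from the spectral decomposition of the reversible rate
matrix, normalised so branch lengths are in expected substitutions/site.

Trees are built with Saitou–Nei neighbor joining; ties in the Q-criterion
break to the lowest index pair, negative branch lengths are clamped to
zero with the deficit logged, and the final three lineages are joined by
the closed-form three-point formulas. BioNJ (variance-weighted pooling)
is available as a flag. Bootstrap support resamples alignment columns
with replacement; replicate r draws from an RNG seeded with `(seed, r)`,
so serial and parallel execution agree and identical seeds give
byte-identical output. Support for each bipartition of the point tree is
the percentage of replicates containing it. Rooting places the root at
the midpoint of the outgroup's branch; supports are re-attached from the
rooting-invariant bipartition map. The optional NNI stage hill-climbs
over nearest-neighbor interchanges under an ordinary-least-squares
branch-length fit (non-negative least squares) and never worsens the
criterion; it is off by default, and the NJ + bootstrap route is the
supported reproduction path, with topology-level (not branch-length)
agreement the stated goal.

Newick output stores supports as integer-percentage internal-node
labels; a display threshold (e.g. show only >50%) affects reporting
only, never topology. Labels containing `|` or `.` survive round-trips.

## Clade analysis

All clade operations require a rooted tree. A query is assigned the
class of the smallest enclosing clade that contains at least one labeled
reference and whose references are all of one class (the query itself
does not vote); if that smallest reference-containing clade is mixed,
the query is `unplaced`. Maximal-clade counting returns the number of
deepest nodes whose entire leaf set satisfies a predicate; singleton
leaves count as clades, consistent with counting collapsed single-leaf
lineages as separate clades in published trees. The concordance report
joins residue labels and clade labels per query and tests ASCL/ORS
reference monophyly.

Note that the non-ASCL/non-ORS type III PKSs form a paraphyletic grade,
not a clade (the cyanobacterial outgroup is itself such a PKS). A lone
"other" query can therefore legitimately attach between its basal
reference and the ASCL+ORS clades and come out `unplaced`; concordance
below 100% on such configurations reflects the biology, not an error.

## Synthetic data generator

`pks3.simulate` emulates the statistical structure of the survey's
input: families of ~300–420 aa proteins carrying (or lacking) planted
features at annotated positions, diverged along random trees. Defaults
(one place, used everywhere):

| parameter | default | meaning |
|---|---|---|
| scaffold_length | 400 aa | typical type III PKS length |
| class mix | 1 ASCL + 2 ORS + 1 other | the bryophyte census configuration |
| class_divergence | 0.3 subs/site | distance from the shared ancestral scaffold to each class scaffold |
| target_height | 0.5 subs/site | root-to-tip divergence within a family |
| indel_rate | 0.01 events/site/sub-unit | modest indel load |
| mean_indel_length | 3 aa | geometric lengths |
| fusion_fraction | 0.1 | share of leaves gaining 50–200 aa random flanks (≈ the share of asterisked fusion entries in the survey's table) |
| outgroup_divergence | 1.5 subs/site | cyanobacterial-style outgroup, rooting only |
| preserve_diagnostics | on | planted sites masked from mutation; indels may neither delete them nor split adjacent planted residues |

Planted layout (1-based on the scaffold): triad C170/H305/N338 (interior,
CHS-like spacing), GFGPG at 370 near the C terminus, ASCL sites G225 +
A240, ORS sites Q218 + V277 + A286; classes other than the site's own
carry Leu (in no allowed set) at that position, and the non-PKS decoy
has the triad Cys and the signature Phe replaced by Ser. Background
residues are drawn from the JTT equilibrium frequencies so evolution is
stationary; substitutions are sampled from P(t) per branch; planted
coordinates are remapped through every accepted indel and recorded in
the truth file.

Random trees are Yule topologies rescaled to the target height, with
internal edges floored at one fifth of the height. The floor makes
simulated topologies *identifiable*: an internal edge far below the
sampling noise of distance estimates carries no recoverable signal, and
a topology-recovery test against such a tree measures the resolvability
of the random draw, not the correctness of the inference. The default
came from a pilot power analysis (100 replicates per candidate floor,
8 taxa, height 0.5, 400 sites): per-replicate NJ recovery was ~95% with
a floor of 0.05 subs/site and ~100% at 0.10 = height/5. Trees are
consequently only approximately ultrametric.

What the generator does **not** emulate: site-rate heterogeneity,
structural/functional constraint beyond the planted sites, composition
bias, alignment uncertainty in real homologs, and real phylogenetic
depth structure. Green tests on synthetic data therefore demonstrate the
correctness of the machinery under the stated model, not classifier
performance on real proteomes; for real data the reference profiles must
be rebuilt from the actual reference sequences.

## Problem sizes and numerical choices

The test suite and the acceptance script run the census at the survey's
own sizes (4 bryophyte-like and 47 algal-like sequences), topology
recovery at 8 taxa × 20 seeded replicates, and pipeline determinism with
100 bootstrap replicates on 13 leaves; the CLI default remains 1000
bootstrap replicates. Distance optimisation tolerance is 1e-8; the
oracle used in tests is an independent likelihood grid at 1e-4
resolution. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; derived seeds stay below 2³¹.

## Known limitations

* The in-house MSA has no refinement; deep, gappy families should use an
  imported alignment.
* Classification at extreme divergence (≳1.5 subs/site) degrades because
  global-alignment numbering transfer becomes unreliable — visible in the
  examples, where the far outgroup fails candidacy and is used for
  rooting only.
* The NNI refinement optimises a least-squares criterion, not likelihood.
* `ambiguous` and `unplaced` are reported, never silently resolved;
  downstream consumers must decide how to treat them.
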