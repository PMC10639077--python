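# Methods

## Evidence aggregation

The unit of evidence is a per-resource record: a TF–gene assertion with a
set of PubMed identifiers (PMIDs) and an optional mode-of-regulation
annotation (activation / repression / unknown).  Aggregation collapses all
records for a (TF, target) pair into one interaction whose `pmids_all` is
the union over resources.  Deduplication is deliberate: the same
publication curated by three databases is one piece of evidence, not three.
The single exception is a PMID asserted with *different* modes by different
resources — it is kept in both the activation and the repression PMID set,
so it contributes to both sides of the later prevalence count.  Records
with an unknown mode support the interaction's existence (they feed
`pmids_all`) but not its sign.  Interactions with no reference at all are
removed before sign assignment.

**Complex merging.**  Dimeric regulators AP1 and NFKB are frequently
referenced by their dimer name in the literature, so evidence must flow
between the dimer entry and its monomer constituents.  The shipped default
map folds the Jun/Fos families (JUN, JUNB, JUND, FOS, FOSB, FOSL1, FOSL2)
into AP1 and the NF-κB subunits (NFKB1, NFKB2, RELA, RELB, REL) into NFKB;
both lists are plain config and overridable, since the exact membership of
these families is a curation choice rather than a fact.  Merging is per
target gene and bidirectional in PMIDs: member evidence is always
attributed to the complex entry (creating the complex edge if necessary),
and complex evidence is attributed back to each member that independently
has an edge to that target.  Complex evidence alone never *creates* member
edges — doing so would assert that every subunit individually regulates the
target, which the dimer-level statement does not support.

**Symbols.**  Gene symbols are uppercased and passed through a user-supplied
alias map (old symbol → current symbol).  The package has no live
dependency on any nomenclature service; keeping symbol currency in a static
map makes builds reproducible and auditable.  PMIDs are opaque strings.

## Regulator filtering

Only regulators classified as DNA-binding (dbTF), co-regulatory (coTF) or
general-initiation (GTF) transcription factors are retained; any one class
suffices.  Classifications ship as static two-column snapshots, merged by
set union over duplicate rows.  AP1 and NFKB are complex names, not gene
symbols, and cannot appear in ontology-derived lists; they are kept through
an explicit whitelist (default `{AP1, NFKB}`).  Targets are never filtered.

## Sign assignment (mode of regulation)

Each interaction receives its sign from the first stage of an ordered
cascade that can resolve it:

1. **PMID prevalence** — `+1` when strictly more distinct PMIDs assert
   activation than repression, `−1` for the reverse.  A tie (including
   0–0) resolves nothing and falls through; prevalence gives no principled
   tie winner, so inventing one would manufacture signal.
2. **Regulon majority** — per TF, the signs obtained at stage 1 are
   tallied; a strict majority classifies the TF as an activator or
   repressor, and that sign is inherited by the TF's unresolved edges.
   At least one PMID-signed edge is required (a majority of nothing is
   nothing), and ties again fall through.  The majority is always computed
   from PMID-stage results on the same input, so removing later stages
   never changes earlier assignments.
3. **Default** — remaining edges get `default_sign`, +1 by default:
   activation is the majority mode among literature-annotated edges, so it
   is the best unconditional guess.

A **prior-knowledge** stage is implemented and can be placed anywhere in
the cascade: TF-level role votes from GO classification, UniProt keywords
and effector-domain characterization, plus a repressor vote when the TF has
a KRAB domain (a canonical repressor domain).  The TF gets a role only if
at least one source votes and all votes agree; missing sources abstain
rather than veto — requiring all four sources to be present would leave the
stage nearly inert, since few TFs carry every annotation.  The stage is
excluded from the default cascade: a TF-level blanket sign conflicts with
the per-edge evidence the earlier stages encode, and in perturbation
benchmarks blanket priors degrade recovery.  Complex regulators participate
in the regulon-majority stage like ordinary TFs; there is no evident reason
to treat a dimer's regulon differently once its evidence is merged.

Every edge carries provenance (`pmid`, `regulon_majority`,
`prior_knowledge`, `default`), and `summarize_network` reports edge-sign
fractions, provenance counts, and the fraction of TFs acting purely as
activators, purely as repressors, or dually.

## Activity scoring (univariate linear model)

For a signature *y* over the measured genes and a TF with signed
target-indicator vector *x* (signed weight on its measured targets, 0
elsewhere), the activity is the slope t-statistic of the OLS fit of *y* on
*x* with intercept, with n − 2 degrees of freedom and a two-sided p-value.
The regression universe is *all* measured genes: the non-targets at 0 are
what make the slope measure enrichment of the TF's targets against the
background, and the intercept absorbs any global shift of the signature
(hence t is exactly invariant under y → a·y + b, a > 0).

Numerical choices: the network is first restricted to genes present in the
signature, and a TF is scored only with ≥ `min_targets` (default 5)
measured targets — below that the slope is dominated by one or two genes.
Duplicate gene rows are averaged with a warning; non-finite values are
dropped per experiment; genes are processed in sorted order so results are
bit-identical under input reordering.  A residual sum of squares at
rounding level (≤ 64 ε · SYY) is treated as an exact fit and yields signed
infinity with a warning; a constant predictor (a TF targeting every
measured gene uniformly, or none) is unscorable and omitted.  Weighted
networks enter as x = sign × weight: the sign orients the edge, the weight
modulates its influence.

`infer_activities` stacks per-experiment scores into an experiments × TFs
matrix (lexicographic columns, NaN for unscored entries) and records each
entry's measured-target count for the size-bias diagnostics.

## Perturbation benchmark

Experiments are filtered for effective perturbation first: a
knockdown/knockout is kept only if the perturbed TF's own log fold change
is ≤ −1 (the boundary −1.0 is retained — the exclusion rule is "greater
than −1"); knockdowns with no recorded logFC are excluded with a warning;
overexpression experiments pass unfiltered.  Experiments whose perturbed
TF the network cannot score are dropped entirely rather than kept as pure
negatives, since each network should be judged on the experiments it can
in principle answer.

Scores are sign-corrected (× direction) so that a *correctly* detected
knockdown contributes a large positive value, flattened in (TF, experiment)
order — fixing this order makes average-precision tie-breaking
deterministic — and labelled positive where the TF matches the experiment's
perturbed TF.  Positives are rare (one per experiment against all scored
TFs), so each permutation draws `min(#pos, #neg)` items from each class
without replacement and computes:

* **AUROC** by pair counting with ties worth ½ (equivalently the
  Mann–Whitney statistic via average ranks);
* **AUPRC** as step-wise average precision — the mean of precision at each
  positive's rank.  Trapezoidal PR interpolation is biased, and average
  precision is the estimator the surrounding ecosystems use; the choice is
  a config-level switch in the sense that `rank_metrics` is a public
  function and can be swapped.

1000 permutations (default) give a distribution summarized by its median.
When classes are already balanced the downsample is the identity and every
sample equals the full-data value.  All randomness flows from one seed;
identical (seed, inputs) give bit-identical results.

The **per-TF benchmark** extracts a single TF's sign-corrected column,
labels the experiments that perturbed it, and runs the same machinery; only
TFs perturbed in ≥ 5 usable experiments are evaluated.  Each TF gets an
independent child stream spawned from the seed, so a TF's result does not
depend on which other TFs happen to be eligible.

The **permuted-network baseline** shuffles the multiset of (target, sign)
pairs against the fixed TF column, preserving per-TF out-degree and the
global sign balance while destroying all biology.  Duplicate (TF, target)
collisions are resolved by random swaps accepted only when they reduce
collisions, with a bounded iteration budget (an error past the budget; in
practice resolution takes a handful of swaps at realistic densities).

**Size bias.**  Per experiment, the Pearson correlation between |activity|
and the TF's measured-target count; reported as the mean over experiments
(experiments with constant values are skipped with a warning — the
correlation is undefined there).  Additionally a two-sided Welch t-test
compares total target counts of benchmark vs non-benchmark TFs.  Welch
rather than pooled-variance because regulon-size distributions are heavy
tailed and the groups are unbalanced.  Multiple-testing correction across
networks is left to the caller, who sees all the raw statistics.

## Binding weights

Raw motif-binding scores (precomputed; motif scanning is out of scope) are
shifted by a pseudocount (default 1, applied uniformly to all scores — the
simplest reading of a pseudocount shift, and configurable) and divided by
the group maximum, grouping either by TF (`per_tf`: weights comparable
within a regulon) or by gene (`per_gene`: comparable across a promoter's
regulators).  Weights land in (0, 1] with exactly one 1 per group, and
normalizing already-normalized weights with pseudocount 0 is the identity.
Pruning removes edges strictly below the global q-quantile of the weight
distribution (q ∈ [0, 1), q = 0 is the identity); the quantile is global
because the pruned object is one pooled weight distribution, but a per-TF
variant is a one-line change in caller code via `RegulonNetwork.regulon`.

## Synthetic ground truth

`simulate_network` draws, per TF, a fixed or uniformly-ranged number of
distinct targets and flips each edge to repression with probability
`repressor_fraction` (default 0.3 — activation-dominant, as curated
collections are).  `simulate_evidence` gives each edge `pmids_per_edge`
PMIDs (default 3, odd to avoid prevalence ties), each annotated with the
true sign flipped independently with probability `sign_error_rate`; a
PMID's mode is a property of the PMID, identical in every resource that
reports it, which is what makes sign recovery a clean majority vote —
with 3 PMIDs and flip rate ε the wrong-sign probability is exactly
3ε²(1−ε) + ε³.  Resources 2..n re-report each pool PMID with probability
`shared_pool_p` (default 0.5) and contribute a private PMID when they would
otherwise be empty, producing the cross-resource overlap that PMID
deduplication exists to handle.  `unreferenced_fraction` blanks that
fraction of records.

`simulate_perturbation` builds a signature in which each target of the
perturbed TF shifts by `direction × edge sign × effect_size` plus
N(0, noise_sd²), every other gene is pure N(0, noise_sd²), and the
perturbed TF's own entry is pinned at `perturbed_tf_logfc` (default −2 for
knockdowns, safely past the −1 effectiveness filter).  Defaults
`effect_size = 3`, `noise_sd = 0.5` describe a strong, clean knockdown;
the default compendium is 20 knockdowns over 200 genes with 20 targets per
TF.

What the generator does *not* emulate: gene–gene correlation, TF–TF
cross-regulation and off-target effects, heavy-tailed or platform-specific
noise, compositional effects of expression normalization, and the research
bias that makes well-studied TFs both better covered and more often
perturbed.  Passing tests therefore demonstrate that the machinery is
correct under its stated model — additive signal in independent Gaussian
noise — not that any particular regulon collection is accurate on real
compendia.

## File formats and reproducibility

All artifacts are tab-separated UTF-8 with header rows and `NA` for
missing values; networks can also be exported as GMT (signs dropped).  The
pipeline runner resolves a YAML config that rejects unknown keys, stamps
its outputs with a config hash and the seed, and funnels all randomness
through that single seed.

## Known limitations

* Signs are global: no cell-type- or condition-specific modes of
  regulation, and no learning of signs from expression data.
* The regulon-majority stage propagates literature imbalance — a TF whose
  repressive edges are under-curated will have its unknown edges called
  activating.
* The univariate model scores TFs independently; shared targets between
  TFs produce correlated activities that the benchmark treats as
  independent observations.
* The effectiveness filter trusts the reported perturbed-TF logFC; absent
  or mis-assigned values silently shrink the benchmark set (with warnings).
* `expand_complex_members` assumes a member symbol belongs to exactly one
  complex.
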