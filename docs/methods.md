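# Methods

`mclprio` prioritizes every protein in an interactome as a candidate drug
target for a *group* of disorders — here, thirteen mental and neurological
disorders linked to the mesocorticolimbic (reward) circuit treated as one
prioritization task. The method combines three families of per-protein
evidence and lets a supervised learner weight them.

## Evidence channels

**Knowledge-based scores** (per disorder, four columns each, plus one
global column):

1. *Biomarker indicator* — 1 if the protein is an annotated biomarker of the
   disorder, else 0.
2. *Interaction inference* — each protein's direct network neighborhood is
   tested for over-representation of the disorder's biomarkers: with degree
   d, b biomarker neighbors, B biomarkers and N proteins in the universe,
   p = P(X ≥ b) for X ~ Hypergeom(N, B, d); the score is −ln p. Degree-0
   proteins score 0.
3. *Pathway enrichment* — every pathway map gets s_P = −ln of its biomarker
   enrichment p (same tail test with the map as the draw); a protein's score
   is Σ s_P over the maps containing it, so membership in several
   biomarker-rich pathways accumulates.
4. *Linear-pathway ratio* — among the ligand→receptor→…→transcription-factor
   signaling chains that contain the protein, the fraction also containing
   at least one biomarker; 0/0 is defined as 0 (a protein on no chain
   carries no chain evidence).
5. *Consortium pathway count* (disorder-independent) — the number of
   consortium-curated pathways the protein appears on.

**Network scores**, seeded with the pooled biomarkers of all disorders (the
disorders are modeled as one task; per-disorder seeding is available):

- *Network propagation*: fixed point of F_t = αW′F_{t−1} + (1−α)Y with
  α = 0.8, Y the 0/1 seed indicator and W′ the symmetric degree
  normalization a_ij/√(d_i d_j). The two normalization phrases used for
  propagation and the random walk differ, and both are honored: propagation
  uses the symmetric kernel, the walk a column-stochastic matrix.
- *Random walk with restart*: fixed point of p_t = (1−r)Wp_{t−1} + rp⁰ with
  restart r = 0.75, p⁰ uniform on the seeds and W column-stochastic
  (a_ij/d_j; a degree-0 column is the identity so mass is conserved).
- *Interconnectivity*: ICN(i,j) = (2·e(i,j) + n(i,j))/√(d_i·d_j) with
  e(i,j) direct adjacency and n(i,j) the shared-neighbor count, averaged
  over the seeds. The denominator's exponent is typeset ambiguously in the
  source description of this score; the square-root degree normalization of
  the original interconnectivity method is adopted here (a documented
  choice). Pairs with a degree-0 member contribute 0.
- *Neighborhood smoothing*: FC′_i = αFC_i + (1−α)·mean of neighbor levels,
  α = 0.5, with the seed level set to 1 on biomarkers.

Both iterative solvers run to a 1e−8 max-norm fixed point (≤1000
iterations, configurable) and are verified in the test suite against the
closed-form linear solves F = (1−α)(I−αW′)⁻¹Y and p = r(I−(1−r)W)⁻¹p⁰.

**Disease-similarity features.** Candidate "similar diseases" are ranked by
−log10 of the hypergeometric tail probability of their gene-set overlap
with the pooled positive-control target set; candidates sharing fewer than
3 targets are ineligible; the top 15 eligible candidates each contribute a
binary is-a-known-target column. Whether biomarker sets or target sets are
overlapped is a config switch (targets by default, since the ≥3-shared rule
is stated for targets); the hypergeometric universe is the full protein
universe.

## Hypergeometric conventions

All enrichment tests use the one-sided upper tail P(X ≥ r), computed in log
space (log-binomials via `gammaln`, combined with `logsumexp`) so universes
up to 10⁶ genes and p-values near 1e−300 are handled without under/overflow.
The ≥ convention is pinned by the worked-example tables: the row with
r = n = 3 has the closed-form single-term tail
(25·24·23)/(15288·15287·15286) = 3.86×10⁻⁹, which matches the reported
value only under ≥. "Log-transformed" scores use the natural log for the
knowledge channels (the base only rescales standardized features) and
log10 for disease similarity, where the quantity is reported as −log10(P).
p-values are clamped to [1e−300, 1] before logging; −log scores are clamped
at 0. The scalar kernel is authored here; the vectorized per-protein hot
paths use `scipy.stats.hypergeom.sf` with kernel↔scipy agreement enforced
by tests.

## Integration

Positive controls are targets associated with ≥2 of the disorders (any
development status). Training uses a balanced nested cross-validation:

- 10 repeats × 5 outer folds; in each outer fold the negative class is a
  fresh uniform sample of non-positive proteins, 10× the training
  positives, so class imbalance is controlled and the random choice of
  negatives averages out.
- The inner loop (5-fold, stratified) performs recursive feature
  elimination on a 2-component PLS regression classifier: at each step the
  feature with the smallest mean |PLS regression weight| across the inner
  folds is dropped and the inner validation error is recorded; the feature
  set minimizing inner error wins (ties → fewer features).
- *Prediction error* is 1 − AUC on the inner validation folds — a
  threshold-free choice consistent with the final ROC evaluation
  (misclassification rate is available via `CVConfig.error_metric`).
- Each outer-fold model (PLS refit on the selected features) scores the
  whole proteome. Within a repeat the five fold scores are averaged and
  converted to genome-wide ranks (ties → average ranks); ranks are averaged
  across repeats into the final score (low = best). Per-feature selection
  counts over the 50 RFE runs (10 repeats × 5 folds) measure feature
  importance on a 0–50 scale.

Evaluation statistics (ROC/AUC, fold enrichment of the top-K list, rank
summaries) are computed on *held-out* genome-wide scores: each protein is
scored only by fold models whose training rows excluded it (positives are
held out in exactly one fold per repeat; the rare protein drawn as a
negative by all five folds falls back to the all-model mean). The final
prioritization itself uses the all-model average, which is what a
practitioner would ship; the held-out variant exists so recovery statistics
are not inflated by training leakage. AUC is the tie-corrected rank-sum
statistic, identical to the trapezoidal ROC area. Fold enrichment is
(hits/K)/(|positives|/N).

PLS fitting and CV splitting use scikit-learn (`PLSRegression`,
`StratifiedKFold`); the RFE-on-PLS-weights procedure, the nested-CV
orchestration and the rank averaging are implemented here. Feature columns
are z-scored once, genome-wide, before modeling — the standardization uses
no label information, so it introduces no leakage; raw values are retained
alongside. Constant columns are dropped with a warning.

## Synthetic knowledge base

The real knowledge base behind this kind of analysis is proprietary, so the
package ships a generator that emulates the statistical structure the
method relies on, with planted ground truth:

- interactome: Barabási–Albert preferential attachment (2000 proteins,
  3 edges per new node at default) — curated interactomes are heavy-tailed,
  and the degree normalizations above exist precisely to correct hub bias;
- one module per disorder, grown by BFS from a random node to 80 proteins;
  biomarkers are sampled inside the module (rate 0.3, plus 5 background
  biomarkers), creating the guilt-by-association signal;
- 50 planted shared targets, each attached to 2–3 disorders' target sets,
  sampled from module members; unique (single-disorder) targets (rate 0.15
  of a module) are kept disjoint across disorders so the planted set is
  exactly the ≥2-indication positive-control set;
- 120 pathway maps (10–40 members, 60% drawn from one disorder module) and
  30 consortium pathways of the same construction;
- 150 linear chains (random simple paths, length 3–8, half started at a
  biomarker);
- 15 eligible similar-disease candidates (3–8 planted targets + 5 other
  disorder targets + 8 random members each) and 5 pure-noise candidates.

Default sizes are a deliberate down-scaling (2000 proteins vs ~18,500
genome-wide) chosen so the full nested CV completes in about a minute; the
in-module enrichment rates have no empirical anchor — the knowledge bases
being emulated publish no such effect sizes — and are documented as
arbitrary values at which the planted signal is recoverable. Generation is
deterministic: the same config and seed serialize to byte-identical files.

What passing tests on this generator do **not** show: real curated networks
have correlated annotation noise, incomplete and biased coverage (well-
studied proteins have more edges, pathways and biomarker links), and
overlapping disease modules none of which the generator reproduces. Recovery
AUC ≈ 0.93 on synthetic data demonstrates that the pipeline's machinery
extracts a planted signal without leaking labels — not that real-data
performance would match.

## Numerical and degenerate-input choices

- Empty seed sets: network scorers return zeros with a warning rather than
  failing, since genome-wide scoring must proceed for disorders with sparse
  annotation.
- Non-convergence raises an error carrying the iteration count (the
  contraction conditions α < 1, r > 0 make this unreachable in practice).
- Ties everywhere are broken deterministically: average ranks in score
  conversion, lexicographic names in enrichment and similarity tables,
  fewer features in RFE.
- Duplicate undirected edges collapse on load; self-loops are rejected and
  counted; isolated proteins stay in the universe (they can still receive
  knowledge and similarity scores).

## Known limitations

- The fold-enrichment arithmetic on the historically reported recovery
  counts (73 of 137 positives in the top 250 of 18,493) gives 39.4 under
  the observed/expected formula; the originally reported 36.6-fold is not
  recoverable from those counts and is therefore reported but never
  asserted.
- Protein complexes and families are modeled as single genes; no ontology
  graph propagation is applied to annotation terms (tables are reproduced
  flat, which is exactly how their (r, R, n, N) inputs are defined).
- PLS is the only learner, by design; the integration procedure is
  PLS-specific.
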