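# mclprio

Multi-evidence drug-target prioritization for mesocorticolimbic (MCL)
disorders — thirteen mental and neurological disorders tied to the brain's
reward circuit, treated as a single therapeutic group.

Given a curated knowledge base (a protein–protein interaction network with
effect/mechanism labels, pathway maps, linear signaling chains, per-disorder
biomarker and drug-target annotations, and candidate similar-disease gene
sets), `mclprio` scores every protein with three families of evidence and
integrates them into one genome-wide target ranking:

- **knowledge-based** — biomarker status; −ln p of hypergeometric biomarker
  enrichment in a protein's direct neighborhood; summed −ln p pathway-map
  enrichment; consortium-pathway membership counts; the fraction of a
  protein's ligand→TF signaling chains that carry a biomarker;
- **network-based** — network propagation (F = αW′F + (1−α)Y, α = 0.8),
  random walk with restart (p = (1−r)Wp + rp⁰, r = 0.75),
  interconnectivity (ICN(i,j) = (2e(i,j)+n(i,j))/√(deg i · deg j) averaged
  over seeds) and neighborhood smoothing (FC′ = αFC + (1−α)·mean neighbor
  FC, α = 0.5), all seeded at the pooled disorder biomarkers;
- **disease similarity** — binary target features from the 15 candidate
  diseases most similar by −log10 hypergeometric overlap (≥3 shared targets
  required).

A 2-component PLS classifier weights the features inside a balanced nested
5×5 cross-validation (10 repeats, negatives resampled per outer fold at 10×
the positives, recursive feature elimination in the inner loop). Per repeat,
fold-model scores are averaged and converted to genome-wide ranks; ranks are
averaged across repeats. Positive controls are targets associated with ≥2 of
the disorders. Because the original knowledge bases are proprietary, the
package includes a synthetic generator with planted ground truth
(`mclprio.synthetic_kb`) so the whole pipeline is testable end to end.

See `docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic knowledge base (2000 proteins, 13 disorder modules, 50
planted multi-indication targets, seed 7), writing small tables to
`results/` and bulky intermediates to `scratch/`:

```sh
python analysis/01_simulate_kb.py
python analysis/02_score_evidence.py
python analysis/03_integrate_rank.py
python analysis/04_evaluate_recovery.py
python analysis/05_enrichment_worked_examples.py
```

Output of the run shipped in `results/` (each step regenerates it):

```
2000 proteins, 5991 interactions (median degree 4, max 125), 50 planted multi-indication targets
feature matrix: 2000 proteins x 72 features
nested CV done: optimal feature count 32 (min prediction error 0.0572)
6 of 72 features selected in all 50 runs
31 of the top 50 ranks are planted targets
cross-validated recovery AUC: 0.930
top 250 of 2000: 42 of 50 planted targets recovered (6.7-fold over baseline)
rank summary of top 250: mean 129.9, median 129.0, min 3.2, max 261.3
direct interactions among the top 250: 267 edges
39 of 39 reported enrichment p-values reproduced at 3 s.f.
```

Reading these numbers: 72 features = 4 knowledge columns × 13 disorders + 1
global pathway count + 4 network scores + 15 similarity binaries. The
error-vs-features curve bottoms out at 32 features — pruning noisy columns
helps up to a point, after which informative ones start being lost. The
held-out AUC of 0.930 means a planted target outranks a random background
protein 93% of the time, and 42 of the 50 planted targets land in the top
250 — a 6.7-fold enrichment over the 50/2000 baseline. The last line checks
the exact hypergeometric kernel against two published top-25 target
molecular-function enrichment tables (e.g. serotonin binding:
r = 7 of R = 25 against n = 11 of N = 15,288 gives p = 4.08×10⁻¹⁸).

The same pipeline is available as a CLI
(`mclprio simulate|score|integrate|evaluate|enrich|run`), e.g.:

```sh
mclprio run --synthetic --seed 7 --out results/run7
```

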