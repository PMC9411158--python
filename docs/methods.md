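# Methods

## Model and assumptions

`comorbnet` predicts disease comorbidity from shared mode-of-action (MOA)
proteins. The underlying assumption is that two diseases co-occurring above
chance in a population do so because they share malfunctioning proteins,
and that those proteins can be teased out without known disease genes by
triangulating two upstream predictions: which drugs are efficacious for
which indication, and which proteins each drug binds. Neither upstream
predictor is part of this package; their outputs (a drug × indication
raw-score matrix and a drug → protein-target map) are its inputs, either
supplied by the user or simulated by the built-in generator.

The pipeline is deterministic given its inputs. Randomness enters only in
the synthetic generator and the permutation nulls, and both draw from a
single configured seed (permutation run *i* uses `rng_seed + i`).

All enrichment tests are one-sided right tails. Both the drug-target
enrichment behind a MOA call ("efficacious drugs bind this protein more
often") and the pair-overlap test ("these diseases share more MOA proteins
than random sets would") are questions of excess; depletion is never of
interest.

## Stage by stage

1. **Standardization.** Raw scores per indication are z-scored against the
   whole drug library with the population (divide-by-N) standard
   deviation: the library is the entire population of probes, not a
   sample. Constant score columns make an indication unusable (empty
   profile, logged).
2. **Partition.** Drugs with Z ≥ `z_cutoff` (default 1.65, the one-sided
   5% point of the standard normal) are called efficacious. The boundary
   is inclusive. This deliberately loose call always yields some
   efficacious drugs with a known false-positive rate.
3. **Per-protein association.** For each protein with at least one binding
   drug, the 2×2 table of (efficacious vs not) × (binds vs not) gives a
   relative risk and a one-sided Fisher exact p. RR conventions: 0 when no
   drug binds the protein, +∞ when only efficacious drugs do.
4. **Tissue filter.** A candidate is dropped only when it has expression
   records in the disease's tissues, every record is "not detected", and
   none is "uncertain". Proteins untested in the related tissues are kept:
   absence of evidence is not a "not detected" call. Diseases with no
   tissue annotation skip the filter.
5. **MOA set.** Survivors with p < `moa_p_cutoff` (default 0.05). q-values
   are computed per disease and carried for ranking only; membership uses
   the raw p. The per-disease q-scope matches how MOA proteins are
   consumed (ranking within one disease); a global scope would couple
   unrelated diseases' significance.
6. **Pair scoring.** Jaccard index of MOA sets, hypergeometric tail p for
   the overlap against the protein universe, q-values across the full pair
   family at once. Edges are emitted for every pair with a significance
   flag (q < `pair_q_cutoff`), so global counts like "significant pairs"
   are derivable from one table. Pairs with an empty profile carry J = 0,
   p = 1.
7. **CoMOAenrich.** Over the top k = min(100, #significant) comorbidities
   (ranked q ascending, J descending, id ascending), each comorbid disease
   sharing protein T contributes min(1, −α ln p) where p is *that
   disease's* MOA p-value for T and α = 0.025. The natural log is forced
   by the implied-p identity e^(−weight/α): a single full-weight
   contribution corresponds to p = e^(−40) ≈ 4.2 × 10⁻¹⁸. The score is
   the weight sum normalized by k; the implied p uses the *unnormalized*
   sum (same identity); the enrichment flag applies the 0.01 threshold to
   the normalized score, strictly.
8. **Pathway over-representation.** One-sided hypergeometric test of the
   top (≤ 100) enriched proteins against each GMT set intersected with the
   universe, q-values across the collection. This is an in-package
   surrogate for an external pathway service, declared as such: it is a
   plain ORA with the universe as background, with no pathway-hierarchy
   awareness.
9. **Benchmarking.** Predictions join clinical counts on the unordered
   pair (intersection; unmatched pairs drop). Easy pairs — efficacious
   drug-set overlap |A∩B|/√(|A||B|) > 0.9 — are excluded first: their
   comorbidity is implied by near-identical drug response and would
   inflate the benchmark. A pair is a clinical positive when
   log RR = ln((n_AB/n_tot)/((n_A/n_tot)(n_B/n_tot))) > 0 (natural log;
   the base affects scale only, never the sign that defines the label).
   Records with n_AB = 0 are excluded (log RR undefined). Metrics:
   Pearson correlation of J with log RR and with the φ-score, recall and
   precision (percent) at the q cutoff, tie-corrected AUROC and step-wise
   AUPRC with J as the continuous score.
10. **Permutation nulls.** Either the drug→target sets or the drug→
    indication score rows are reassigned among drugs by a uniform random
    bijection (multisets preserved), and the whole pipeline reruns;
    `n_permutations` (default 100) runs give a null mean and sd per
    metric, z = (observed − mean)/sd, and a one-sided upper-tail normal p.
    A null run can leave a metric undefined (e.g. no predicted positives →
    precision undefined, or constant J → correlation undefined); summaries
    are nan-aware and a metric with too few defined null values reports
    z = nan rather than failing.

## Parameters

| parameter | default | units / meaning |
|---|---|---|
| `z_cutoff` | 1.65 | z-units; one-sided 5% efficacy call |
| `moa_p_cutoff` | 0.05 | probability; MOA membership |
| `pair_q_cutoff` | 0.05 | FDR; significant comorbidity |
| `alpha` | 0.025 | enrichment weight coefficient |
| `top_k_comorbid` | 100 | comorbidities used by CoMOAenrich |
| `enrich_score_cutoff` | 0.01 | normalized score; "enriched" flag (strict >) |
| `easy_pair_cutoff` | 0.9 | cosine-style drug-set overlap (strict >) |
| `n_permutations` | 100 | permutation runs per null |
| `clinical_n_tot` | — | cohort size; shared by all clinical rows, lives in config |

## q-values

Storey's method with the λ grid 0.05–0.95 (step 0.05) and a cubic-
polynomial smoother for π₀ evaluated at λ = 0.95, falling back to
Benjamini–Hochberg (π₀ = 1) when the family has fewer than 100 tests or
the smoothed estimate leaves (0, 1]. The fallback keeps small simulated
families well-defined; on large families of uniform p-values the smoother
exceeds 1 and the fallback applies as well. Output q-values preserve the
p-value ordering and are clipped to [0, 1].

## Numerical choices

- Hypergeometric/Fisher/binomial/normal tails use scipy's log-gamma
  implementations; the binomial tail is summed exactly (integer binomial
  coefficients) up to n = 1000 so boundary identities hold bit-exactly.
- p-values are floored at 1e-320 before any logarithm, keeping enrichment
  weights finite.
- TSV writers use `%.17g` (exact double round trip); readers parse
  numerics through numpy's correctly-rounded string→float conversion
  because pandas' fast parser can be off by one ulp.
- Ties: edge ranking is (q asc, J desc, pair lexicographic); enrichment is
  (score desc, protein asc); pathway results are (p asc, pathway asc).
  Betweenness splits equally over equally short paths; closeness is
  computed within a node's component as (reachable nodes)/(Σ hop
  distances); both via networkx, unweighted.
- Degenerate inputs: all-zero 2×2 tables return p = 1; J of two empty sets
  is 0; an empty MOA profile is legal and propagates as J = 0, p = 1.

## The synthetic world

The generator emulates every input the pipeline touches, with the truth
planted so recovery is measurable. Reference conditions: 300 drugs, 2000
proteins, 40 diseases, module size 25, score effect δ = 3 against unit
Gaussian noise, 8 planted comorbid pairs sharing 50% of their modules,
clinical cohort of 10⁶ with a 5× relative-risk boost on planted pairs.

Free design choices, fixed once:

- Each drug is focused on one disease and draws 22 of its 25 targets from
  that disease's module plus 3 background proteins, so its score effect
  (δ × in-module fraction ≈ 2.6) clears the efficacy cutoff for most
  focused drugs. The drug→disease assignment is balanced (round-robin,
  then shuffled): probe libraries are designed for coverage, and a
  Poisson assignment could leave a disease with no focused drugs at all,
  i.e. a module that was never actually planted in the data.
- Tissue levels are drawn with "not detected" at 10% and reliability
  "uncertain" at 10%, so the tissue filter is exercised but rarely removes
  a true module protein (~1% per protein-disease); the filter's logic has
  its own dedicated tests.
- Disease prevalences are uniform on 0.5–5%; co-occurrence counts are
  binomial draws at RR × independence, capped at the feasible margin.
- The pathway collection contains every planted module plus 40 random
  decoy sets of the same size.

What the generator does **not** emulate: pharmacological realism (real
drugs are promiscuous and hub proteins recur across diseases), correlated
noise between indications, ontology structure among diseases, or realistic
tissue-expression patterns. Passing recovery tests therefore shows the
machinery is correct and well-calibrated on separable planted structure;
it does not certify performance on real predictor outputs, where signal is
far weaker and confounded.

At these conditions (seed 1) the pipeline recovers 97% of planted module
proteins, separates planted from unplanted pairs with AUROC ≈ 0.997, and
the observed J/log-RR correlation stands about 10 null standard deviations
above the drug→indication permutation null — figures recomputed, not
asserted, by `scripts/acceptance.py` and the test-suite.

## Known limitations

- The permutation nulls propagate through this package's pipeline only.
  In the original setting the drug→protein permutation is followed by
  re-running the upstream indication predictor, which partially restores
  drug–disease information and makes that null *less* destructive than
  the drug→indication one. Without the upstream predictor the two
  permutations are distributionally equivalent here (each is a bijection
  between efficacy profiles and target sets), so the package makes no
  claim about their relative severity — only that each destroys planted
  signal.
- Whether the protein universe counts genes or isoforms is decided by the
  universe file the user supplies; all overlap statistics scale with it.
- The pathway test is a flat ORA; topology- or hierarchy-aware statistics
  are out of scope.
- Identifiers are opaque strings; mapping between vocabularies (ICD,
  DOID, MeSH) must happen upstream.
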