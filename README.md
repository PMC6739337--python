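# sigrank

Consensus ranking and psychoactive-enrichment statistics for
compound–proteome interaction signatures.

## The problem

Shotgun drug repurposing compares every compound against every protein
in a structural library at once: each compound is reduced to an
*interaction signature* — a vector of real-valued compound–protein
interaction scores — and compounds with similar signatures are inferred
to behave similarly. Given the signatures of the drugs already approved
for an indication, nearby compounds in signature space are repurposing
candidates for it. This package implements the downstream analysis for
asking a specific question of such a matrix: **are psychoactive
compounds (phenethylamines, tryptamines, cannabinoids) preferentially
predicted for mental-health indications**, relative to randomized
controls?

It is written for computational drug-repurposing practitioners: the
input is any dense compound × protein score matrix (TSV or Matrix
Market) plus compound/indication metadata tables, and every stage is
exposed both as a library function and as a `sigrank` CLI subcommand.

## The statistics

For an indication with k approved drugs, each drug contributes its TopX
most similar compounds by signature RMSD,

    RMSD(a, b) = sqrt( (1/P) Σ_i (a_i − b_i)² ),

and a candidate's **consensus count** is the number of approved drugs
whose TopX list contains it (≤ k); its **percent occurrence** is
100·count/k. Enrichment is summarized by two consensus-weighted
percentages:

* **normalized indication rank** — psychoactive share of an
  indication's total consensus mass;
* **normalized compound rank** — mental-health share of a compound's
  total consensus mass.

Worked example: a psychoactive (ergoline) predicted 7× for Pica
(mental health) and 3× for stomach pain, a non-psychoactive (aspirin)
predicted 4× and 6×. Compound ranks: 100·7/(7+3) = **70%** (ergoline),
100·4/(4+6) = **40%** (aspirin). Indication ranks: 100·7/(7+4) =
**64%** (Pica), 100·3/(3+6) = **33%** (stomach pain).

Observed distributions are compared against two permutation controls
(predicted-compound relabelling with consistent replacement, and
mental-health label permutation; 1000 replicates each by default) using
one-tailed Kolmogorov–Smirnov and paired-t tests, and indication pairs
sharing ≥2 psychoactives above a per-TopX consensus threshold
(2/3/4/6 at Top10/25/40/100) form an association network.

A synthetic-cohort generator with planted enrichment (latent signature
clusters, psychoactive-bearing clusters, cluster-coherent indications)
makes the whole pipeline testable without external data.

## A worked run

```python
import sigrank as sr
from sigrank.synthetic import SyntheticSpec, generate_cohort

spec = SyntheticSpec(seed=42, enrichment=0.9)      # planted enrichment
matrix, compounds, indications = generate_cohort(spec)
config = sr.AnalysisConfig(topx_values=(10, 25),
                           association_thresholds={10: 2, 25: 3},
                           n_randomizations=200, seed=42)
summary = sr.run_pipeline(matrix, compounds, indications, config)
r = summary.per_topx[10]
print(f"{r.observed_mean_indication_rank_mh:.2f}")                  # 8.33
print(f"{r.null_compound_shuffle_mean_indication_rank_mh:.2f}")     # 2.53
print(f"{r.ks_indication_rank_vs_compound_shuffle['p_value']:.3g}") # 1.62e-44
```

Reading: across the 120 mental-health indications of this synthetic
cohort, psychoactives contribute on average 8.33% of the consensus mass,
against 2.53% after the predicted compounds are randomized — an excess
the one-tailed KS test finds far beyond chance. (The absolute
percentages are small because only 2.5% of the cohort's compounds are
psychoactive.) At Top25 the observed mean falls to 4.96% against a 2.48%
null: longer lists dilute the psychoactive signal, the expected behaviour
as list size grows.

The same run from the shell:

```
sigrank generate --out-dir data --seed 42
sigrank run --matrix data/matrix.tsv --compounds data/compounds.tsv \
            --indications data/indications.tsv --seed 42 --reps 200 \
            --out-dir results/run
sigrank run --fixture worked-example --out-dir results/toy   # 70/40/64/33
```

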