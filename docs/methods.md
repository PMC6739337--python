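# Methods

## The model

The analysis treats each compound as a *compound–proteome interaction
signature*: a real-valued vector of interaction scores against a fixed
protein panel. The working hypothesis is that compounds with similar
signatures behave similarly in vivo, so a compound whose signature is
close to the signatures of drugs approved for an indication is a
repurposing candidate for that indication. Nothing in the pipeline uses
target annotations or indication–protein links; everything flows from
signature similarity.

Similarity is root mean squared deviation over the full panel,

    RMSD(a, b) = sqrt( (1/P) * sum_i (a_i − b_i)^2 ),

with no per-protein weighting and no special treatment of protein
classes, so scores from different protein families are directly
comparable. Smaller is more similar. Raw scores are compared as stored;
no centring or normalization is applied before the RMSD (a deliberate
choice, kept because rank order under RMSD is what the downstream
statistics consume and any monotone rescaling shared by all compounds
leaves the ranks unchanged).

### Consensus prediction

For an indication with k approved drugs, each drug contributes its TopX
most similar compounds (X in {10, 25, 40, 100} by default; ties broken
by case-folded identifier so runs are reproducible across platforms; the
query is excluded from its own list). A candidate's **consensus count**
is the number of approved drugs whose TopX list contains it — at most k
— and its **percent occurrence** is 100 · count / k. Candidates that are
themselves approved for the indication are kept and flagged, preserving
the "at most k predictions" accounting. Psychoactive compounds never act
as queries (they are barred from approved lists at validation), but
always appear as candidates: predictions run from approved
non-psychoactive drugs toward psychoactives, never the reverse.

### Enrichment statistics

Two consensus-weighted percentages summarize psychoactive enrichment:

* **normalized indication rank** (per indication): psychoactive share of
  the indication's total consensus mass,
  100 · Σ_psy count / Σ_all count;
* **normalized compound rank** (per compound): mental-health share of
  the compound's total consensus mass across indications.

Both are weighted by consensus counts, not by distinct compounds — the
two-compound worked example (counts 7/3 and 4/6 giving 70/40 and 64/33
percent) fixes this reading. Values are carried at full precision;
display rounding is half-up to integer percent. Entities with zero total
consensus mass are omitted rather than scored zero. Epilepsy-tree
indications are flagged mental-health in the indication table (pooling
them with the psychiatric tree); the flag is data, so users can override
the pooling.

### Randomized controls

Two Monte-Carlo nulls, 1000 replicates by default, averaged per entity:

* **compound shuffle** — per replicate and per indication, the distinct
  predicted compounds are relabelled by an injective uniform draw from
  the whole library; each replacement inherits the original's entire
  consensus count (consistent replacement), then both rank statistics
  are recomputed. Injectivity (sampling without replacement within an
  indication) is a design choice: the alternative with-replacement
  reading can collide two originals onto one replacement and change the
  consensus structure it is supposed to preserve.
* **indication shuffle** — per replicate, mental-health labels are
  permuted across indications (count preserved) and compound ranks
  recomputed.

Per-replicate values are retained alongside the means so tests can
compare an observed distribution against either the replicate-averaged
null (the display convention) or the pooled per-replicate values (the
correct reference for calibration, since averaging shrinks the null's
spread toward its mean).

### Significance tests

Both tests are one-sided with the alternative "observed stochastically
greater than null". The KS statistic is D+ = sup_x [ECDF_null(x) −
ECDF_obs(x)] with the asymptotic tail bound p = exp(−2 m n D+² /
(m+n)). This bound is conservative: on samples small enough to
enumerate, every rejection it makes is confirmed by exhaustive
permutation, and disagreement is confined to a narrow band just above
the threshold on the retain side. The paired t-test aligns entities
(indications or compounds) between observed and null means and tests
mean(observed − null) > 0; degenerate zero-variance differences are an
error, not a silent p-value. No multiple-testing correction is applied
across TopX levels; raw p-values are reported.

### Association networks

Two indications are associated when at least two distinct psychoactives
are predicted for both, each clearing a per-TopX minimum consensus count
in *both* endpoints (≥2 at Top10, ≥3 at Top25, ≥4 at Top40, ≥6 at
Top100). The per-endpoint reading of the threshold is deliberate: an
"either endpoint" reading also reproduces the printed two-compound
example at τ=2 but admits asymmetric, weaker links. Edges default to
mental-health indication pairs (flag to include all); the export is an
edge list plus an optional circular-layout plot rather than a chord
diagram.

### Compound classification

Psychoactives are classed by parent-scaffold substructure (SMARTS)
matching with priorities: cathinone (β-keto α-methyl phenethylamine) >
amphetamine (α-methyl phenethylamine) > phenethylamine > tryptamine >
cannabinoid (5-alkylresorcinol core, plus a fused benzopyran pattern).
The phenethylamine benzylic position admits sp³ carbon or carbonyl so
the β-keto family stays nested inside it: every cathinone match is an
amphetamine match is a phenethylamine match, and priority resolves the
overlap. Molecules matching nothing are "other". The published pattern
files behind the original 291/109/149/20/6 partition are not available,
so these rules are reconstructions from the parent-molecule definitions;
they are configuration (YAML), not code, and reproducing that exact
partition is out of scope. α-ethyl cathinones (e.g. buphedrone) fall
outside the α-methyl hierarchy and classify as phenethylamine under the
default rules.

## The synthetic cohort

The generator emulates the statistical structure the analysis exploits,
not the marginal distribution of real docking scores.

* **Clusters.** Compounds belong to latent groups; each signature is its
  group centroid plus iid Gaussian noise (sd `noise_sd`, default 0.05).
  Centroids sit on orthogonal coordinate blocks scaled so the minimal
  centroid RMSD is max(10 · noise_sd, 1): "similar signature ⇒ same
  group" holds by construction. One group per compound (hard
  clustering); real chemistry is messier, but hard structure gives
  assertable ground truth.
* **Psychoactives.** A subset of groups is psychoactive-*bearing*; each
  bearing group hosts a configurable number of flagged members (default
  one), the rest being ordinary compounds eligible as approved drugs.
  This is forced by the analysis direction: if a whole cluster were
  psychoactive, no member could serve as the approved drug whose
  neighbourhood predicts the others.
* **Indications.** Each indication draws all its approved drugs (default
  3) from a single group — drugs approved for one indication are assumed
  to share a mechanism, hence a signature cluster. A mental-health
  indication picks a bearing group with probability `enrichment` and a
  non-bearing group otherwise; other indications pick uniformly. Setting
  `enrichment` to the base rate (bearing fraction of groups) therefore
  reproduces the uniform assignment *exactly*, making mental-health
  labels exchangeable — the no-effect calibration point. `enrichment=1`
  routes every mental-health indication through a psychoactive-bearing
  cluster — the planted effect.
* **Defaults** (the study conditions for all tests): 720 compounds in 60
  clusters of 12 over 120 proteins; 18 bearing clusters with one
  psychoactive each (base rate 0.3, psychoactive prevalence 2.5%); 480
  indications, 25% mental-health, 3 approved drugs each; enrichment 0.9;
  all randomness from one seed through named generators.

The cluster count and bearing coverage matter for calibration: under the
label-permutation control the psychoactives' (disjoint) indication sets
share a fixed-count label vector, which negatively correlates their
mental-health fractions and deflates the observed ECDF's variance
roughly in proportion to the bearing coverage. With coverage 0.3 and 18
near-independent psychoactive profiles the one-sided KS at α = 0.05
rejects in ≈4–5% of unenriched cohorts (measured over three independent
200-cohort batches); denser coverage drives the test conservative.

What the generator does **not** emulate: realistic docking-score
marginals, soft/overlapping chemical classes, correlated noise across
proteins, indications whose drugs span several mechanisms, and
psychoactive prevalence at the real study's ~11% (prevalence is tied to
one-psychoactive-per-cluster here). Passing tests therefore demonstrate
that the statistics behave correctly under the similarity structure the
method assumes — not that the biological claims about any particular
compound hold.

## Numerical choices and degenerate inputs

* Neighbour ties broken by case-folded identifier; identifiers
  whitespace-trimmed and case-folded on ingest, duplicates rejected.
* Missing matrix entries are an error with coordinates, never imputed.
* Indications with no usable approved drugs are skipped with a logged
  warning at prediction; an indication table whose approved lists cite
  psychoactives or unknown compounds fails validation outright.
* Zero-total-consensus entities are omitted from rank distributions.
* The compound shuffle requires the library to span the predicted
  compounds (which also guarantees injective replacement is possible);
  the indication shuffle refuses an all-identical label vector.
* KS p-values are clipped to [0, 1]; the paired t refuses zero-variance
  differences and unaligned samples.
* Report sizes used by the test suite, chosen to keep the full run in a
  few minutes on one CPU: 200 unenriched cohorts with 50-replicate nulls
  for calibration; 20 seeds with 200-replicate compound shuffles for
  planted-effect recovery; 10 seeds with 100-replicate nulls for the
  two-control contrast (the contrast cohort gives mental-health
  indications 9 approved drugs, mirroring the larger repertoires of real
  mental-health indications, since the two controls coincide in mean
  when all indications carry equal consensus mass).

## Known limitations

* The asymptotic one-sided KS p is a bound, not an exact tail; at very
  small samples use the permutation enumeration (as the tests do).
* The compound-shuffle control is not distribution-matched to observed
  data even absent enrichment (it destroys the clustering of
  psychoactive flags), so calibration statements attach to the
  label-permutation control; the compound shuffle is the effect-size
  reference.
* Scaffold rules are reconstructions; class tallies on real libraries
  will differ from the original publication's partition.
* The indication-association stage is near-degenerate on the default
  synthetic cohort (one psychoactive per cluster rarely yields two
  shared qualifying psychoactives); use `psychoactives_per_group > 1`
  cohorts or real tables to exercise it at scale.
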