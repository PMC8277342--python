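# Methods

## Pipeline

The analysis turns a table of free-text entries — an obsession description
plus optional trigger, exposure and compulsion texts per submission — into a
clustered 2D semantic map of the corpus's most frequent words. Stages run in
a fixed order:

1. **Outlier-user removal.** Users contributing more than
   `max_entries_per_user` entries (default 100) are dropped entirely; a
   handful of extreme contributors would otherwise dominate both the
   co-occurrence statistics and the frequency comparisons.
2. **Phrase assembly.** Each entry's texts are concatenated into one phrase,
   lowercased, and split on any non-alphanumeric character (hyphens and all
   punctuation act as separators). Spelling correction is an explicit
   user-supplied token→token map, not an algorithm: misspellings in
   clinical free text are domain-specific, and a silent auto-corrector
   would be harder to audit than a reviewable substitution list.
3. **Lemmatization.** Pluggable `word -> lemma` callable. The bundled
   default is a small English lookup table tuned to this domain
   (wash/check/germ/door inflections and common plural nouns), with identity
   fallback; any heavier NLP toolchain can be dropped in. The table maps
   inflections directly to final lemmas, so lemmatization is idempotent.
4. **Vocabulary.** Frequency = total token occurrences across all entries
   (not per-user document frequency). Ranking is by descending frequency
   with lexicographic tie-breaks, making the top-fraction cut reproducible.
5. **Analysis-word selection.** The top `ceil(fraction · N)` ranked words
   (default fraction 0.07, mirroring how a several-thousand-word free-text
   vocabulary is thinned to a visualizable few hundred), then a
   part-of-speech filter removing closed-class and low-content categories
   (Penn tags RB/RBR/RBS, MD, VBZ, VBG, VBN, TO, IN, PRP via a pluggable
   tagger, lookup default), then an optional reviewed exclusion list kept as
   a versioned one-word-per-line file so the manual curation step stays
   automatable and auditable.
6. **Co-occurrence.** X_ij counts phrases containing both words: the window
   is the whole phrase, increments are unweighted, duplicates inside a
   phrase count once (set semantics; a flag switches to multiplicities),
   diagonal is zero. Short app entries are unordered bags of symptom words,
   so distance weighting within the phrase would be meaningless.
7. **Embedding fine-tuning.** See below.
8. **Projection and clustering.** PCA (mean-centred SVD) of the analysis
   words' fine-tuned vectors to two components; each component's sign is
   fixed so its largest-magnitude loading is positive. k-means (k-means++,
   10 restarts, 300 iterations, tol 1e-6) runs on the 2D map by default —
   clustering the same coordinates that are plotted and that the stability
   analysis measures distances on — with a switch to cluster in the full
   embedding space for sensitivity checks.

## Embedding model

For every ordered pair with X_ij > 0 the objective fits
w_i·w̃_j + b_i + b̃_j ≈ log X_ij, weighted by f(x) = min((x/x_max)^α, 1),
plus the retrofitting penalty μ Σ_{i∈R} ‖(w_i + w̃_i) − r_i‖² pulling words
toward their pretrained reference vectors. Defaults: x_max=100, α=0.75,
learning rate 0.05 (the standard GloVe recipe), μ=0.1 (the standard
retrofitting weight), 1000 epochs, d matched to the pretrained table. The
penalty applies to the summed representation ŵ = w + w̃ — the vector
actually used downstream — with a config switch to penalize w alone.

Choices that matter numerically:

* **Optimizer.** Deterministic full-batch AdaGrad in the standard
  accumulate-then-update form: a += g², θ -= lr·g/(√a + 1e-8), with
  accumulators starting at zero. This bounds every component's first step
  by the learning rate. The update-then-accumulate variant used by
  per-observation stochastic trainers diverges here: with pretrained dot
  products (~10) far above the log-count scale (~2), the first full-batch
  gradient is orders of magnitude too large for an unscaled step.
* **Initialization.** Words with a pretrained vector start at
  w = w̃ = r/2 (so ŵ starts exactly at r and the penalty starts at zero);
  the rest start uniform in [−0.5/d, 0.5/d], as do all biases, from a
  single seeded generator — identical seeds give bit-identical fits.
* **Zero counts are skipped** (log 0 undefined), matching the objective's
  domain; μ=0 reduces exactly to plain GloVe on the local corpus, and
  μ→∞ pins ŵ to the pretrained table (both are tested).

## Cluster-number selection

Four heuristics per candidate k (default range 2..8): maximize silhouette,
maximize Calinski-Harabasz, minimize Davies-Bouldin, and the elbow rule
implemented as the interior k maximizing the discrete second difference of
inertia — deterministic and dependency-free, with ties to the smallest k.
The consensus is the mode of the selections, ties again to the smallest k
(preferring the more parsimonious solution). A report flags weak structure
when even the best silhouette is below 0.25.

Known limitation: Calinski-Harabasz systematically over-splits maps that
have a diffuse central convergence area. With three tight theme clusters
bridged by shared central words, the k=3 within-cluster scatter is
dominated by the bridge words, so CH often gains by carving the centre into
its own cluster (k=4–6) even when every other heuristic and the planted
truth say 3. Davies-Bouldin, silhouette and the elbow are robust to this
geometry, and the CH+DB consensus (ties to the smaller k) selects the
planted number reliably.

## Split-half reliability

The corpus is split into equal halves — chronologically at the cut point
balancing cumulative word counts, or by users assigned greedily
(largest contributor first, shuffled by seed) so user sets are disjoint —
and the *entire* pipeline reruns independently per half, from vocabulary
selection through PCA. For each word shared by both halves' analysis
vocabularies, the correlation is computed between its vector of Euclidean
distances to all other shared words in map A and the same vector in map B,
excluding the self-distance (a constant zero in both rows would distort r).
Distance profiles are invariant to each half's arbitrary rotation,
reflection, translation and (through Pearson r) global scale, so no
Procrustes alignment is needed. The summary reports the per-word
distribution (median, fraction ≥ 0.90) plus a single whole-matrix
correlation over the vectorized upper triangles; zero-variance rows are
reported as missing with a warning.

## Frequency statistics

Per cluster: unique-word count and total token count (sum of member words'
corpus frequencies). Comparisons use the chi-square goodness-of-fit test
against equal expected frequencies (df = c−1, no continuity correction),
omnibus over all clusters and pairwise with Bonferroni adjustment for the
C(k,2) family. The pairwise convention (two-category GOF) is this package's
own; both measures are exposed because unique-word and token-mass
imbalances answer different questions.

## Synthetic corpus generator

The generator emulates the statistical structure of symptom-tracking app
data so every stage is testable without access to any real corpus:

* **Users and entries.** Default 2000 users; entries per user follow a
  heavy-tailed categorical distribution with mode 1 — P(1)=.67, P(2)=.17,
  P(3)=.07, P(4)=.03, P(5)=.02, the remaining 4% spread over 6–10 — so
  ~96% of users contribute five or fewer entries, matching the shape of
  real per-user histograms; optional outlier users (rate 5e-4) contribute
  `outlier_size` (default 120) entries to exercise outlier removal.
  Timestamps are sampled uniformly (distinct seconds) over a fixed
  ~28-month window so chronological splits are meaningful.
* **Themes and core.** `k_true` latent themes (default 3), each with a
  30-word lexicon; a 10-word shared core lexicon (~10% of the vocabulary)
  models the harm-like words every theme uses. Each user belongs to one
  theme; each token is core with probability `core_mix` (default 0.2),
  otherwise theme. Phrase lengths are categorical over 1–8 tokens, skewed
  short (most app entries are a few words).
* **Pretrained vectors.** Theme centroids sit at (separation/√2)·e_t, which
  makes all pairwise centroid distances exactly `separation` (default 10);
  theme words scatter around their centroid with isotropic Gaussian noise
  (`noise_sd`, default 0.5). Core words are placed at random convex
  combinations of the theme centroids (symmetric Dirichlet weights) plus
  the same noise: a diffuse central convergence area *between* the theme
  clusters, the way shared clinical vocabulary actually behaves, rather
  than a tight fourth blob that the cluster-number heuristics would
  rightly count as its own cluster.
* Texts are whitespace-joined clean tokens; a `dirty` flag injects random
  casing and punctuation to exercise the cleaning stage.

What the generator does **not** emulate: real English morphology and
grammar (lemmatization and POS filtering are exercised by dedicated unit
fixtures instead), polysemy, theme overlap at the user level (each
synthetic user has exactly one theme), vocabulary growth over time, and
the long Zipf tail of real free text (the planted lexicon is closed, which
is why pipeline runs on synthetic corpora use `top_fraction=1.0`). Passing
tests therefore demonstrate that the machinery recovers known structure
under realistic sampling noise — not that any particular clinical corpus
has three subtypes.

## Scales used in the shipped analyses

The acceptance script and end-to-end tests use 2000-user corpora
(~3700 entries, 100-word vocabulary), 50-dimensional synthetic pretrained
vectors, 1000 training epochs and 20 independent seeds — sizes chosen so a
full 20-seed replication completes in well under a minute on one CPU while
leaving the planted-structure recovery far from threshold (observed
split-half median r ≈ 0.998 against the 0.90 criterion; consensus k = 3 in
every seed tried). Dimension 50 rather than 100 halves the cost with no
qualitative change; both are configurable.

## Degenerate inputs and guards

Empty corpora, empty vocabularies, all-zero count vectors, k outside
[2, n−1], fewer points than PCA components, and malformed vector-file lines
raise informative errors. Calinski-Harabasz returns +inf when within-cluster
scatter is exactly zero (so rankings still prefer it); Davies-Bouldin skips
coincident-centroid pairs with a warning; silhouette scores singleton
clusters 0; zero-variance distance rows are dropped from the reliability
report with a warning.
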