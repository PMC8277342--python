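# ocdtext

Data-driven discovery of semantic subtypes of obsessions from short
free-text reports.

People with obsessive-compulsive disorder describe their obsessions in their
own words — "germs on door knobs", "did I lock the door", "I might hurt
someone" — and symptom-tracking apps collect such entries from tens of
thousands of users. Rather than sorting these reports into a predefined
symptom checklist, `ocdtext` lets the subtypes emerge from the language
itself: it embeds the reported words in a semantic vector space adapted to
the clinical corpus, maps them to two dimensions, and clusters them. The
package is aimed at computational-psychiatry and clinical-NLP researchers
who have a table of (user, timestamp, free text) entries and want a
reproducible, testable subtype analysis.

## The model

Entries are cleaned and concatenated into phrases, and a symmetric
co-occurrence matrix X counts, for every pair of words, the number of
phrases containing both. Word vectors are then fit to the GloVe objective
with a retrofitting penalty (the Mittens extension) that anchors them to
pretrained general-language vectors r_i:

```
J = Σ_{i,j: X_ij > 0} f(X_ij) (w_i·w̃_j + b_i + b̃_j − log X_ij)²
    + μ Σ_{i ∈ R} ‖(w_i + w̃_i) − r_i‖² ,      f(x) = min((x/x_max)^α, 1)
```

optimized by deterministic full-batch AdaGrad; the final representation is
ŵ = w + w̃. The most frequent words (top fraction of the lemmatized,
POS-filtered vocabulary) are projected onto their first two principal
components and clustered with k-means; the number of clusters is chosen by
four heuristics — silhouette, elbow (maximal discrete second difference of
inertia), Calinski-Harabasz, Davies-Bouldin — combined by a mode-consensus
rule. Reliability is assessed by splitting the corpus in half
(chronologically or by users), rerunning the entire pipeline per half, and
correlating each word's vector of distances to all other words between the
two 2D maps. Cluster word frequencies are compared with chi-square
goodness-of-fit tests.

Because raw app data cannot be redistributed, the package ships a synthetic
corpus generator that plants a known number of semantic themes, a shared
"harm-like" core lexicon bridging them, a heavy-tailed entries-per-user
distribution, and a matching synthetic pretrained embedding table — so the
whole pipeline is testable end to end with a known ground truth.

## Worked example

```python
from ocdtext import (SyntheticSpec, generate_corpus,
                     generate_pretrained_embeddings, PipelineConfig,
                     run_pipeline, run_model_selection, kmeans,
                     cluster_frequency_table, chisq_gof,
                     split_half_stability)

spec = SyntheticSpec(n_users=2000, k_true=3, separation=10.0,
                     noise_sd=0.5, core_mix=0.2, seed=1)
entries = generate_corpus(spec)
pretrained = generate_pretrained_embeddings(spec)

cfg = PipelineConfig(top_fraction=1.0)   # planted lexicon = closed vocabulary
result = run_pipeline(entries, pretrained, cfg)
report = run_model_selection(result, range(2, 9), seed=1)
print(report.selected_k, report.consensus_k)

sol = kmeans(result.projection, report.consensus_k, seed=1)
table = cluster_frequency_table(sol.labels, result.vocab)
print(table.unique, chisq_gof(table.counts("unique")).statistic)

stab = split_half_stability(entries, pretrained, cfg, mode="by_user", seed=1)
print(stab.median_r, stab.fraction_above)
```

prints

```
{'silhouette': 3, 'calinski_harabasz': 4, 'davies_bouldin': 3, 'elbow': 3} 3
{1: 34, 2: 34, 0: 32} 0.08
0.998 1.0
```

Three of the four heuristics recover the three planted themes and the
consensus is k=3 (Calinski-Harabasz leans toward splitting the central
core-word bridge — see `docs/methods.md`). The three clusters contain 32–34
words each; with near-equal planted lexicons the omnibus chi-square is, as
expected, tiny (χ²=0.08, not significant — on real data, unequal cluster
sizes make this test informative). The split-by-users reliability check
gives a median per-word distance-profile correlation of r=0.998, with 100%
of words above r=0.90.

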