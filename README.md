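# comorbsig

Cross-disease transcriptomic signature comparison: given case/control
expression cohorts from two diseases, `comorbsig` derives a
differential-expression (DEG) signature per disease, quantifies how strongly
the two signatures overlap in each direction, and characterizes the shared
genes through network hub analysis and gene-set / transcription-factor
over-representation.

It was built around a comorbidity question — why schizophrenia (SCZ)
patients develop type 2 diabetes (T2DM) at elevated rates — studied through
peripheral-blood (PBMC) transcriptomes: two SCZ cohorts (13 vs 8 and 43 vs 29
case/control samples) combined by effect-size meta-analysis, one T2DM cohort
(12 vs 24) analyzed with a moderated t-test, compared over a shared
background of measured genes. The package re-implements that workflow as a
tested, reusable library with a synthetic-data generator that plants known
structure, so every stage can be validated end-to-end without any data
download.

## What it computes

**Per-disease signatures.**
For a single cohort, per-gene two-group tests use empirical-Bayes variance
moderation: the pooled variance $s_g^2$ ($d_g$ residual df) is shrunk toward
a prior $(s_0^2, d_0)$ fitted across genes by digamma/trigamma moment
matching,

$$\tilde s_g^2 = \frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g},\qquad
\tilde t_g = \frac{\bar x_{g,\mathrm{case}} - \bar x_{g,\mathrm{ctrl}}}
{\tilde s_g \sqrt{1/n_1 + 1/n_0}} \sim t_{d_0 + d_g}.$$

For several cohorts of the same disease, each contributes Hedges'
bias-corrected standardized mean difference $g_i$ with variance $v_i$, and
genes are combined with the DerSimonian–Laird random-effects model
($Q$, $\tau^2$, weights $w_i^* = 1/(v_i + \tau^2)$, combined effect
$\mu$, $z = \mu/\mathrm{SE}$). Both arms use Benjamini–Hochberg FDR with a
strict FDR < 0.1 call.

**Directional overlap.** The two signatures are partitioned into up/up,
down/down and the two discordant intersections over the shared background of
$N$ genes. Each partition reports the representation factor
$\mathrm{RF} = k \,/\, (n_A n_B / N)$, a one-tailed (enrichment-directional)
Pearson chi-square p-value, and the exact hypergeometric upper tail
$P(X \ge k)$ as oracle.

**Network hubs.** Shared DEGs plus an undirected interaction edge list form
a gene network; hubs are the top 20 % of nodes by degree (number of distinct
neighbors), count rounded up, ties broken lexicographically.

**Over-representation.** Query lists are tested against GMT gene sets or
TRRUST-style TF regulons with the hypergeometric upper tail, Bonferroni
correction (< 0.05), and redundancy clustering by Cohen's kappa (threshold
0.3) with the lowest-p term representing each cluster.

**Synthetic studies.** `SynthSpec` describes a two-disease design (default:
2000-gene universe, the three cohort shapes above, planted DEGs with
concordant overlaps of 7 up / 21 down and discordant 2 + 4, effects of
1.2 per-gene SDs); generators emit expression matrices, gene sets, edge
lists and regulons with recorded ground truth.

## Worked example

```bash
comorbsig run --seed 1 --out run/
```

runs the full synthetic study — simulate, meta-analyze disease A, test
disease B, overlap, hubs, enrichment — and prints:

```
run complete; manifest at run/manifest.json
  n_deg_disease_a: 65
  n_deg_disease_b: 87
  overlap_partitions: {'up_up': 3, 'down_down': 10, 'upA_downB': 1, 'downA_upB': 2}
  n_network_nodes: 48
  n_hubs: 10
  n_significant_terms: 2
  n_term_clusters: 2
  n_significant_tfs: 2
```

65 and 87 genes pass FDR < 0.1 in the two disease arms (64 and 122 were
planted; the small 12-vs-24 cohort has limited power, see
`docs/methods.md`). The concordant overlaps are strongly enriched — from
`run/overlap.tsv`, the down/down partition has k = 10 against an expectation
of 1.03 (RF = 9.7, one-tailed chi-square p = 6.0e-20, exact hypergeometric
p = 2.3e-8) — while the discordant partitions stay near chance. The network
over the shared DEGs and their interactors has 48 nodes, hence
ceil(0.2·48) = 10 hubs, and the planted gene-set term and regulator rank
first in their enrichment tables. `run/manifest.json` records config hash
and per-file checksums; rerunning with the same seed reproduces them
exactly.

Each stage is also available separately (`comorbsig simulate / dge / meta /
overlap / hubs / enrich / tf`) and as plain library calls.

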