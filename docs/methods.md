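# Methods

## The task and the network

The package predicts drug–disease associations (DDAs) by combining two
information channels for every molecule: what it *is* (attributes
computed from its own data) and how it *behaves* (its position in a
heterogeneous molecular association network, MAN). The MAN is an
undirected graph over five node kinds — drug, disease, protein, miRNA,
lncRNA — and nine association kinds. All edges carry unit weight: the
sources these networks are assembled from report presence/absence of an
association, not strength. The weight field is retained so the same
machinery works on weighted networks.

Identifier normalization is deliberately minimal: whitespace trimming
everywhere, case-folding for disease names only (MeSH headings are
capitalised inconsistently across sources; accession-style drug,
protein and RNA identifiers are case-sensitive in their home
databases). Duplicate edges collapse to one rather than accumulating
weight, consistent with the unit-weight convention. Nodes that appear
only in attribute files are kept in the attribute store but are not
graph nodes; an embedding requires connectivity, so an isolated
molecule cannot be scored (this is also why per-fold cold-start pairs
are dropped, below).

## Disease semantic similarity

Each disease's MeSH tree numbers induce an ancestor DAG: every prefix
of every tree number is an ancestor. A member d contributes
C_e(d) = max over DAG children d′ of ε·C_e(d′), with C_e(e) = 1 — i.e.
contribution decays by ε per step along the *shortest* ancestor path.
Two diseases are compared by the normalized sum of contributions over
shared members (SV₁). Properties maintained and tested: SV₁ is
symmetric, SV₁(e,e) = 1, and adding a shared ancestor can only raise
similarity.

ε defaults to 0.5, the standard choice in this family of DAG-decay
similarity measures; it is exposed in configuration. A tree-number
prefix with no descriptor in the table is skipped with a warning (the
chain reconnects at the nearest present ancestor). A disease absent
from the table is flagged "no DAG" and handled by the missing-attribute
policy.

The per-disease attribute is its row of the full pairwise SV₁ matrix
brought to width 64. With more than 64 diseases the row is compressed
by the stacked autoencoder; with at most 64 diseases the row is
zero-padded instead — padding is lossless and deterministic, and
training a compressor whose output is wider than its input is not
meaningful. Either way every node kind ends up with a uniform 64-wide
attribute.

## Sequence and structure attributes

Protein and ncRNA sequences are reduced to a 4-letter alphabet (four
physicochemical amino-acid groups; A/C/G/U with T mapped to U), then
all overlapping 3-mers are counted and normalized: 4³ = 64 bins summing
to 1. Residues outside the alphabet are removed before windowing and
the removal is logged; a cleaned sequence shorter than 3 cannot produce
a window and is flagged.

Drug SMILES are converted to Morgan fingerprints (radius 2, 1024 bits —
the community defaults) and compressed 1024 → 256 → 64 by a stacked
autoencoder: symmetric single-hidden-layer sigmoid autoencoders trained
greedily (each layer's code is the next layer's input) under mean
squared reconstruction error with plain minibatch SGD (lr 0.01, batch
16, 50 epochs per layer, Glorot-style seeded init). These settings are
configuration-surfaced; the defaults were chosen for stable convergence
at the scale of hundreds-to-thousands of drugs, not tuned per dataset.

Missing-attribute policy: a node whose raw data is absent or unusable
(unparseable SMILES, too-short sequence, no MeSH entry) keeps a zero
64-vector and a flag. Flagged drugs/diseases are excluded from
classifier pairs — a zero vector would silently poison the forest —
but stay in the graph, where their edges still inform other nodes'
embeddings.

## LINE embeddings

First- and second-order proximity are trained separately at half the
total width (default 64 total → 32 + 32) and concatenated first-then-
second; concatenation follows the original LINE practice. Training
draws edges proportionally to weight from the directed expansion of the
undirected edge set (so both endpoints of an edge are treated
symmetrically across draws) and pairs each positive draw with K = 5
negatives sampled proportional to degree^0.75. The learning rate decays
linearly from 0.025 to 1% of itself over the sample budget (default
100·|E| draws per order). Dot products are clamped to ±35 before
exponentiation.

Numerical choice worth recording: the vectorized trainer accumulates a
minibatch of per-sample gradients before applying them. On small graphs
a large batch concentrates many updates on the same few nodes and the
combined step diverges (observed as exploding norms). The effective
batch is therefore capped at max(16, |V|/2), which restores the ~one-
update-per-node-per-step regime of sequential SGD while keeping large-
graph batches fully vectorized.

The exact objectives L₁ = −Σ ω·log σ(u_a·u_b) and
L₂ = −Σ ω·log softmax(c_b·u_a) (both directions of each edge, full
softmax over all context vectors) are implemented separately as a
small-graph oracle (guarded at |V| ≤ 2000) together with a full-
gradient descent mode; the sampled trainer is validated against them in
the tests rather than trusted on faith.

## Pairs, classifier, cross-validation

Positives are the known drug–disease edges; negatives are unobserved
(drug, disease) pairs sampled uniformly without replacement at a 1:1
ratio. The balanced ratio is a design choice: it makes sensitivity and
specificity comparable and is the usual convention when the true
negative rate is unknown. Feature rows are the concatenation
[drug attribute | drug embedding | disease attribute | disease
embedding]; the two ablation variants select the corresponding 128
columns of the *same* rows, built from the same pairs, folds, seeds and
per-fold embeddings, so a variant comparison isolates the feature
family.

The classifier is a random forest with n_estimators = 100 and
max_depth = 110 (grid-searched values; all other parameters are library
defaults with a fixed seed). AdaBoost, logistic regression and Gaussian
naive Bayes are drop-in alternatives behind the same score-in-[0,1]
interface.

Cross-validation is stratified five-fold. The default is *leakage-safe*:
each fold's held-out positive edges are removed from the graph before
that fold's embedding is trained, and their absence is asserted.
Embedding the full graph once (`leakage_safe=False`) is cheaper and
mirrors evaluation setups that do not re-embed, but it lets test edges
shape the features and inflates AUC; the flag exists precisely to make
that difference measurable. A node whose every edge was held out has no
embedding in that fold (cold start); its pairs are dropped from that
fold with a warning. Metrics with zero denominators are reported as NA,
never coerced to 0; the fold dispersion is the sample standard
deviation; AUC is the trapezoid area under the threshold-sweep ROC,
which equals the normalized Mann–Whitney U statistic (asserted in
tests). Ranking queries for one disease first delete that disease's
drug edges and re-embed before scoring, with ties broken
lexicographically by drug id.

## Synthetic data generator

The generator emulates the premise of the method — that association
patterns among the five molecule kinds carry drug–disease signal — as a
planted-community model. Default scale: 40 drugs, 60 diseases, 120
proteins, 60 miRNAs, 30 lncRNAs (the proportions of the real multi-
source compilations at roughly 1/50 scale, keeping the full pipeline in
seconds on one CPU), 10 balanced communities spanning all kinds, and a
fixed per-kind edge budget (~1750 edges) whose relative sizes follow
the real compilations (drug–disease, protein–disease and miRNA–disease
densest). Edge budgets rescale with node counts so reduced-scale test
networks keep the same densities.

Each association kind draws its budget as: a `signal` share of distinct
pairs sampled without replacement from the within-community pool, the
remainder uniform over all pairs. `signal` is therefore literally the
fraction of associations explained by community co-membership;
signal = 0 is an edgewise-uniform null with no structure. The quota
design (rather than independent per-pair Bernoulli draws) keeps the
planted fraction exact, and — because the within-pool is largely
exhausted at the default budget — most unobserved within-community
pairs become positives rather than negatives, so the recovery task has
a clean information ceiling well above the evaluation bound used in the
tests. The community count (10) was chosen from that ceiling analysis:
fewer communities leave too many within-community negatives, more make
communities too small to embed reliably.

Attributes carry the same ground truth: sequences of a community share
a Dirichlet-drawn group-frequency profile; drugs of a community prefer
one scaffold and terminal group (SMILES are assembled from a
scaffold + linker + terminal grammar and verified parseable at
generation time); diseases of a community sit under one top-level
branch of the generated MeSH-style tree, so SV₁ correlates with
co-membership. A 10% share of true drug–disease pairs is held out of
the network and returned as ground truth for ranking experiments.

What the generator does *not* emulate: realistic degree distributions
(real association networks are heavy-tailed; the planted model is
closer to homogeneous within blocks), realistic chemistry beyond
parseability, sequence homology structure, or label noise. Passing the
recovery tests therefore shows the pipeline can extract a known
community-mediated signal without leakage — it does not certify
performance on real heterogeneous data, whose signal is sparser and
less cleanly block-structured.

## Determinism and problem sizes

One master seed derives independent stage seeds (attribute
autoencoders, negative sampling, fold assignment and per-fold embedding
seeds, classifier) through `numpy` seed sequences; two runs of the same
configuration produce bit-identical reports, embedding dumps and
simulated datasets. The test suite and the acceptance script run the
full pipeline at the default ~310-node scale (about 500 labeled pairs,
five leakage-safe re-embeddings per variant set), which completes in
tens of seconds on a single CPU; the same code paths scale to the
thousands-of-nodes regime of the real compilations, where the exact-
softmax oracle is unavailable (guarded) and only the sampled trainer is
used.

## Known limitations

- Negative sampling assumes unobserved pairs are true negatives; some
  are undiscovered positives, which biases all metrics pessimistically.
- Disease attributes depend on a flattened MeSH table supplied by the
  user; the official XML is not parsed.
- The SAE is a plain sigmoid/SGD implementation — adequate at this
  feature scale, but no substitute for a modern deep-learning stack if
  fingerprints grow to tens of thousands of bits.
- Cold-start molecules (no edges, or all edges held out) cannot be
  scored, only flagged.
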