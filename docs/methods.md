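# Methods

## Models

### Translation-family embeddings

Entities and relations are vectors in ℝᵈ. The score of a triple *(h, r, t)*
is a distance, lower = more plausible:

- TransE: d(h, r, t) = ‖ĥ + r̂ − t̂‖ (L2 by default, L1 optional).
- TransR: d(h, r, t) = ‖Mᵣĥ + r̂ − Mᵣt̂‖ with a learned d×d matrix per
  relation. Projection matrices are initialized to the identity: a zero or
  random initialization either kills gradients or destroys the early
  translation signal, while the identity start makes TransR a strict
  refinement of TransE.
- Squared vs unsquared distance: both appear in the literature for this
  family. The package defaults to the **unsquared** L2 distance for every
  translation method and exposes `squared_distance` as a config option. The
  unsquared form keeps gradient magnitude independent of the current
  distance scale and makes TransE/TransR scores directly comparable; in our
  parameter-recovery experiments the squared form also generalized worse at
  desk scale (large-distance pairs dominate the updates).

### Joint numerical-attribute embedding (TransEA / TransRA)

Numeric literals *(e, l, v)* are fit by a linear head v̂ = ê·l̂ + b̂ₗ with a
per-attribute vector l̂ and scalar bias b̂ₗ. The attribute loss is the
squared residual by default (`absolute` optional; squared gives smooth
gradients). The total loss is the convex mix

    L = (1 − α) L_relation + α L_attribute ,  α ∈ [0, 1], default 0.3.

With α = 0 the attribute pass is skipped entirely, so TransEA reduces
*exactly* to TransE and TransRA to TransR — including identical consumed
random streams, which the tests assert bitwise. TransRA uses TransR's
projection for the relational part and the same linear literal head;
attribute prediction always reads the unprojected entity vector.

### ComplEx

Entities and relations are complex vectors; the score is the real part of
the trilinear product with the tail conjugated, Re Σᵢ ĥᵢ r̂ᵢ conj(t̂ᵢ),
higher = better. ComplEx is trained under the same margin-ranking scheme as
the translation methods by negating scores into distances; a logistic loss
(softplus on ±score) is available via `loss="logistic"`. A
`ComplEx_numerical` variant attaches the same linear literal head to the
real part of the entity embedding; it is flagged experimental since the
coupling is not canonical.

## Training

Plain SGD, margin ranking with one corrupted triple per positive:

| parameter | default | notes |
|---|---|---|
| dimension d | 32 | matches the generator's latent dimension |
| margin γ | 1.0 | hinge margin on distances |
| α | 0.3 | attribute loss weight (attribute methods) |
| learning rate | 0.01 | constant |
| epochs | 500 | desk-scale default |
| batch size | 128 | |
| negatives/positive | 1 | |
| norm constraint | on | entities projected to ‖ê‖ ≤ 1 after each batch (off for ComplEx) |
| negative policy | bernoulli | see below |

Initialization is uniform in [−6/√d, 6/√d] per coordinate, entity rows then
projected into the unit ball. All randomness flows from one seed through
four independent spawned generators (initialization, batch order, negative
sampling, attribute pass), so traces are bitwise reproducible and the
attribute pass cannot perturb the relation-side stream.

**Negative sampling.** The default `bernoulli` policy corrupts the head
with probability tph/(tph + hpt) per relation (tails-per-head /
heads-per-tail). For 1-to-N relations this mostly corrupts heads, which
avoids repeatedly sampling the relation's own true or held-out tails as
false negatives — the standard companion of the TransR lineage, and
decisive at desk scale where each entity is hit often. `uniform` (50/50)
is available.

**Loss trace.** The per-epoch mean combined loss is recorded. Because
negatives are resampled each epoch, the trace is noisy near zero; the
monotonicity check used in the tests compares 5-epoch window means with a
slack of 5% *of the initial loss level* — a relative tolerance is
ill-defined as the hinge loss approaches zero.

## Multihop derivation

Relation-type paths of length 2..max_hops realized by at least
`min_support` distinct **simple** entity paths (no repeated entities — this
prevents cycle blowup and derived self-loops from 2-cycles) are
materialized as composite triples (start, "r1|r2|…", end). The separator
`|` is reserved and rejected in input relation IRIs at parse time
(`allow_composite=True` re-admits it when loading an already-augmented
graph). Inverse steps are supported and marked `^r`, off by default —
calculation chains point forward. Composite relations are excluded from the
path alphabet, making derivation idempotent. Support counting is at the
instance level; a schema-level filter would slot in at
`enumerate_relation_paths` if class information were available.

## QA workflow

Entity linking is a fuzzy name search: Levenshtein distance (edlib)
normalized to similarity 1 − d/max(len), over primary labels, chemical
formulas and aliases, case/whitespace-normalized; for whole questions, word
n-grams (up to 4 words) are tried as candidate mentions. Relation
prediction is template matching: templates with `{head}` placeholders are
compiled to wildcarded regexes, with a fuzzy fallback above threshold 0.55;
the predictor is a pluggable callable, so a learned question-to-relation
model fills the same contract. Candidates are the n-hop neighborhood of the
head, traversed **undirected by default** since answers in deep ontologies
can sit on inverse paths; the hypothetical triple still scores the
candidate as tail. Ranking negates distance-polarity scores so everything
is higher-is-better; ties break by entity id.

Numeric qualifiers are parsed by regular expressions into
larger / smaller / close operators ("at 100 K" counts as close); τ for
"close" defaults to 5% of |value|. Units are compared as normalized literal
strings — no unit conversion.

**Two-round filtering.** Round 1 keeps entities whose *predicted* value
satisfies the operator with slack δ (smaller: v̂ < value + δ; larger:
v̂ > value − δ; close: |v̂ − value| ≤ τ + δ); round 2 keeps survivors whose
*stored* value satisfies it exactly. δ defaults to 2 sample standard
deviations of the per-attribute training residual v̂ − v, targeting
high round-1 recall; δ = ∞ disables round 1 and reduces the pipeline to an
exact scan. Entities without a stored value are returned in a separate
`no_data` list, never silently dropped.

## Evaluation

rank = 1 + (# strictly better) + tie share; the tie policy defaults to
**average** (half the tied block) so a constant-score model cannot achieve
perfect metrics; optimistic/pessimistic are available. "Filtered" names two
distinct protocols, kept separate because both senses are common:
*filtered-link-prediction* removes candidates t′ ≠ t with (h, r, t′) known
true in train ∪ test before ranking; *gold-head* supplies the true head to
the QA pipeline instead of entity linking. Either can only improve on its
raw counterpart, and every report names its protocol.

## Score alignment

The model family is the smallest one faithful to "predict a per-answer bias
from the question-ontology affiliation and the domain": per ontology a
scale w_o > 0 and bias weights u_o over binary bag-of-words features plus
an intercept, applied to max-normalized scores:

    s′ = w_o · s_norm + u_o · φ(q).

Training is pairwise hinge (margin 0.1, SGD, 200 epochs, seeded), pushing
each gold answer above all non-gold answers; w_o is clamped ≥ 0.01 so the
adjustment is monotone within an ontology — only the cross-ontology
interleaving can change. Both the multiplicative scale and the additive
bias are learned; either can be frozen by construction. Affiliation is
exposed separately as a per-ontology naive-Bayes classifier over word
presence; with no recognized words it returns the training base rate
exactly.

## Synthetic data: what it emulates, and what it does not

The generator plants recoverable structure: entities carry latent vectors;
each relation links a head cluster to a tail cluster; a tail's latent is
placed at mean(latents of its actual heads) + translation + jitter/3, so
the geometry encodes the realized edges, not just cluster membership —
without this, linked and unlinked same-cluster tails are geometrically
indistinguishable and no trainer could separate them. Half the relations
are 1-to-N with truncated-geometric fan-out (mean 6, minimum degree 2 per
side); real chemistry ontologies are denser still. Attribute values are
linear reads v = z·l* + b* + N(0, σ²), σ = 0.05 by default, 90% coverage.
Deep chains (species → calculation → result → value, depth 3) follow their
step translations exactly, so a latent-built "exact space" scores chain
triples at distance 0. Labels are pronounceable pseudo-chemical names with
formula aliases; question sets instantiate templates over held-out triples,
with optional single-character mention misspellings and disjoint
train/test template splits.

Default conditions: 200 entities, 8 relations (3 of them chain steps),
3 attributes, 10 chains, d = 32, test fraction 0.2.

What passing these benchmarks does **not** show: real ontologies have
schema constraints, correlated relations, non-linear attribute
dependencies, heavy-tailed label noise, and scale (10⁵–10⁶ triples); real
questions have paraphrase variety no template set covers. Results here
demonstrate correctness of the machinery and recoverability of planted
structure, not expected accuracy on production knowledge graphs.

## Numerical and degenerate-input choices

- Distance gradient at d = 0 is set to 0 (guarded by a 1e-12 floor).
- Negative sampling with a corrupted entity equal to the original
  contributes no loss and no update.
- Max normalization of a score list whose maximum is ≤ 0 maps the list to
  zeros with a logged warning.
- The N-Triples subset carries no unit slot; units survive only the TSV
  dialect.
- Serialization orders triples by (head id, relation id, tail id); floats
  are written with `repr` so TSV roundtrips are exact.

## Known limitations

- SGD is single-threaded numpy; desk scale only (≈10³–10⁴ triples).
- TransR-family training cost is dominated by the d×d projection updates.
- The template relation predictor is a contract stand-in for a learned
  model; it cannot generalize across paraphrases outside its template set.
- No unit conversion in numeric filtering.
- ComplEx with the numerical head is experimental; joint literal modeling
  helps the translation family far more than the bilinear one on these
  benchmarks, consistent with its design.
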