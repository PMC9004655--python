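# Methods

## Model family and score orientation

A knowledge graph is a set of facts (h, r, t) over typed entities
(`type-serial` identifiers such as `gene-00001`). Three structure
embeddings are implemented — TransE (`S = h + r − t`), TransH (head and
tail projected onto the hyperplane with unit normal w_r before the
residual), ConvKB (ReLU feature map of 1×3 filters slid over the rows of
[h; r; t]) — and three fusion schemes that combine S with the category
difference C = h_c − t_c and the description difference D = h_d − t_d.

Scores are oriented so that **higher f means more plausible**; the margin
loss `ReLU(γ − f⁺ + f⁻)` and all ranking code follow that convention.
The reverse hyperplane projection score is

    f = −‖S‖² + Σ_M λ_M ‖M − S*ᵀM S*‖²,   M ∈ {C, D}.

Design choices where the formulation leaves room:

- **Normalization of S\*.** The default is the unit normal
  `S* = S/‖S‖₂`, under which the modal term is the exact squared
  orthogonal component of M (the geometric reading of a hyperplane
  projection). A variant `snorm="squared"` with `S* = S/‖S‖₂²` is retained
  in the scoring API and gradient code because the quadratic form appears
  in some statements of the method; both are tested, the unit form is
  default everywhere.
- **Degenerate hyperplane.** If S is exactly the zero vector it has no
  direction; the modal residual is then defined as the zero vector. This
  only matters at contrived parameter settings but keeps scoring total.
- **ConvKB modal residual.** S is a k×n_f matrix while C, D are
  k-vectors; the residual is computed per filter column (column j uses the
  unit column S_j as its normal), the only reading under which
  `vec(M − S*ᵀM S*)` has the k·n_f entries that `W_S` expects. `vec` is
  column-major (filter-major), and `W_S` is stored in the same order.
- **Forward HP.** The baseline projects S sequentially onto the
  hyperplanes normal to the unit category then description vectors, each
  projection scaled by its λ, and returns −‖S′‖² (ConvKB: −W_Sᵀvec(S′)).
  Whether λ sits inside or outside the projection is a genuinely open
  choice; applying it inside (S′ = S − λ(m·S)m) makes the λ → 0 limit
  coincide smoothly with the structure-only score, which the reverse
  scheme also satisfies, so the two baselines meet at λ = 0.
- **Cross-embedding.** The residual convention `h + r − t` is used for
  the substituted terms as well (a `cross_residual="flipped"` switch flips
  to `h − r + t`). Modal terms are weighted by their λ so the four
  S/S+C/S+D/S+C+D configurations are expressed uniformly; at λ = 1 the
  unweighted sum is recovered.

## Parameters

| parameter | default | meaning |
|---|---|---|
| k | 32 | embedding size (100–200 on corpus-scale graphs; desk-scale default) |
| γ | 1.0 | ranking margin (grid {0.2, 0.6, 1.0} in large-scale practice) |
| n_f | 10 | ConvKB filters |
| lr | 1e-3 | Adam learning rate (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) |
| λ_C, λ_D | 0 | modal weights; 0 disables a modality (configuration S) |
| batch fraction | 1/40 | batch size = max(1, ⌊|train|/40⌋), the fixed protocol rule |
| max epochs | 200 (library) / 1000 (corpus-scale protocol) | training length |
| init bound | (−6/k, 6/k) | literal Glorot boundary; `init_mode="classical"` switches to ±√6/√(2k) |

Conv filters all start at (0.1, 0.1, −0.1); divergence between filters
arises through the score-weight coordinates during training, no jitter is
added. TransH relation normals are re-normalized to unit length after
every optimizer step (the score formula presumes unit normals; the
original soft-constraint penalties are not reproduced). W_D is trained
jointly with the structure parameters; the description *features* φ(e)
are fixed inputs — text encoding is out of scope, any encoder's vectors
can be supplied.

Gradients are analytic NumPy for every backbone × fusion combination and
flow **through** the normalization S* (it is not treated as a constant);
all paths are validated against central finite differences (≤1e-5
relative on the raw scores, ≤1e-4 through the losses).

## Training protocol

80/10/10 random split, followed by a greedy coverage repair: any
validation/test triplet containing an entity or relation absent from
train is moved into train, so every identifier is seen during training
(realized fractions are therefore ≥ the nominal train fraction). One
Bernoulli negative per positive: the head is corrupted with probability
tph/(tph+hpt), the replacement is uniform over the vocabulary, and draws
are rejected (up to 100 retries) if they collide with any known true
triplet in train ∪ valid ∪ test. Margin loss for TransE/TransH, softplus
for ConvKB. Validation filtered MR is computed every `eval_every` (50)
epochs and the best-MR snapshot is returned. Grid search is full
factorial over the supplied axes, minimizing validation MR, ties to the
earliest grid point. Everything is deterministic given the seed.

## Evaluation

Filtered entity prediction: two queries per test triplet; every
vocabulary entity is scored in the open slot; candidates other than the
answer that form a known triplet (train ∪ valid ∪ test) are removed;
rank = 1 + #strictly-better + ⌊#ties/2⌋. The mid-rank tie rule matters
because ConvKB's ReLU produces exact ties at initialization. Candidates
are not restricted to the answer's type by default (a type-restricted
mode exists). The headline MR averages both directions; per-direction
means are reported alongside.

Typed-pair completion scores all (head-type, tail-type) pairs under every
relation, keeps the per-pair maximum, excludes pairs already linked in
*train* (so held-out pairs can legitimately surface), and returns the top
⌊0.1·|train|⌋. Association Precision is the pooled ratio
Σ_d |T_d ∩ P_d| / Σ_d |T_d| with P_d truncated to |T_d| — not a
per-disease mean.

## Synthetic study conditions

The generator plants a graph a translational model can provably fit:
entity latent positions z live in an 8-dimensional space organized as
type centers (gene / drug / disease) containing sub-cluster **modules**;
relation r carries a translation v_r between a source and a target type;
a triplet (h, r, t) is emitted only if ‖z_h + v_r − z_t‖ ≤ ε. Module
offsets are **shared across types**, so a relation's translation lands on
the module of the target type corresponding to the head's module — the
way a gene module is linked to the drug module acting on it. Category
labels name an entity's type and module, each replaced by a uniformly
random label with probability 1 − `category_signal`; description vectors
are a fixed random linear map of z plus Gaussian noise.

Scales were chosen from two constraints, computed before running any
experiment end to end: *identifiability* — the expected number of
within-ε tail candidates per (h, r) should be small (≈12 at the defaults:
per-dimension variance 2·0.25², ε = 0.75, so P(‖·‖ ≤ ε) ≈ 0.18 over ~66
same-type tails), otherwise ranking is ambiguous by construction — and
*feasibility* — the total pool of placeable triplets (relations × heads ×
candidates) must comfortably exceed `num_triplets`. Placement enumerates
the feasible pool exactly and samples uniformly from it, failing fast
with the pool size when the request cannot be met.

Default conditions (200 entities, 5 relations, 2000 triplets, latent
dim 8) are the learning-sanity setting: TransE with k = 32 reaches
held-out filtered MR ≈ 14 after 300 epochs versus ≈ 100.5 for random
parameters.

The **category-driven** conditions (`category_driven_config`: 120
entities, 4 relations, 350 triplets, ε = 0.6, 5 modules per type,
signal 0.9) put the graph in the regime where annotations pay:
~3 training facts per entity leave the per-entity structure vectors
data-starved, while the per-label category vectors pool evidence across a
whole module. There, reverse-HP S+C at λ_C = 0.2 (TransH, γ = 2.0)
improves mean held-out MR over structure-only across seeds, and
scrambling the annotations across entities — which preserves the label
marginals exactly — removes the advantage. The larger margin matters:
with γ = 1 the modal term alone can satisfy the margin on easy negatives
and the structure term stops training, washing out the benefit.

What the generator does **not** emulate: realistic degree distributions
(real biomedical graphs are heavy-tailed; planted graphs are roughly
uniform), a realistic relation inventory (corpus graphs have ~67
relations), annotation vocabularies with hierarchical ontology structure,
or any textual content behind the description vectors. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
direction of multimodal fusion on planted structure — not effect sizes on
real corpora.

## Known limitations

- The category-fusion advantage on the synthetic family is small
  (fractions of a rank at MR ≈ 10) and seed-sensitive; some seed triplets
  show no advantage. The scrambled-annotation control behaves correctly
  throughout (no advantage ever). Real-corpus effect sizes cannot be
  inferred from these runs.
- The reverse-HP modal bonus is relation-agnostic (C and D do not depend
  on r except through the hyperplane), so label-pair reward learned under
  one relation bleeds into others; with few, type-segregated relations
  this is mostly harmless, but it is a structural property of the score.
- Training is desk-scale, single-process NumPy; no GPU or distributed
  path.
- Entities without the `type-serial` identifier pattern get type
  `unknown` and are excluded from typed-pair inference only.
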