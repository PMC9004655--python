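# kgfuse

Multimodal knowledge-graph embedding for biomedical link prediction:
translational structure models (TransE, TransH, ConvKB) fused with entity
**category** annotations and precomputed **description** feature vectors via
reverse hyperplane projection, with filtered mean-rank evaluation and
typed-pair knowledge-graph completion (drug–gene, gene–disease,
disease–drug inference).

## The problem

Biomedical knowledge graphs store facts as triplets *(h, r, t)* — a head
entity, a relation, and a tail entity, e.g. *(gene-00123, associate,
disease-00007)*. Link prediction asks which unobserved triplets are
plausible: candidate disease genes, drug repurposing hypotheses, drug–gene
interactions. Entities additionally carry annotations — discrete category
labels (entity type, ontology terms) and free-text descriptions — that are
informative about linking behaviour but ignored by purely structural
embedding models. `kgfuse` implements structure embeddings together with
three fusion schemes that inject the annotation modalities into the
triplet score.

## The model

Every entity and relation gets a k-dimensional vector. A triplet's
**structure embedding** S is a residual that is small when the fact is
consistent with the learned geometry:

- TransE: `S = h + r − t`
- TransH: `S = (h − wᵣᵀh·wᵣ) + r − (t − wᵣᵀt·wᵣ)` with a unit normal `wᵣ`
  per relation, so entities take relation-specific representations
- ConvKB: `S = ReLU([h; r; t] ∗ Ω)`, 1×3 filters Ω slid over the rows of
  the stacked k×3 matrix, giving a k×n_f feature map

The **category embedding** of a triplet is `C = h_c − t_c`, where `e_c` is
the mean of the learned vectors of an entity's category labels; the
**description embedding** is `D = h_d − t_d` with `e_d = W_Dᵀ·φ(e)` for a
fixed precomputed feature vector φ(e) (any text encoder output) and a
learned d×k matrix `W_D`. Missing annotations map to zero vectors, so
partially annotated graphs degrade gracefully.

**Reverse hyperplane projection** treats the structure embedding itself as
a hyperplane normal `S* = S/‖S‖` and scores (higher = more plausible)

    f(h, r, t) = −‖S‖² + Σ_{M ∈ {C, D}} λ_M · ‖M − S*ᵀM·S*‖²

penalizing the structure residual while rewarding the components of the
annotation differences that lie *on* the structure hyperplane. For ConvKB
the analogue is `f = −W_Sᵀvec(S) + Σ λ_M W_Sᵀvec(M − S*ᵀM·S*)` with the
modal residual taken per filter column. Two baselines are included: the
forward **HP** scheme (annotation vectors as hyperplane normals, structure
projected onto them) and **cross-embedding** (modal vectors substituted
for the endpoints inside the translational residual).

Training minimizes a margin ranking loss `Σ ReLU(γ − f⁺ + f⁻)` (TransE /
TransH) or a softplus logistic loss `Σ log(1 + exp(−y·f))` (ConvKB) with
Adam, one negative per positive drawn by the Bernoulli trick: the head is
corrupted with probability `tph/(tph + hpt)` so non-1-to-1 relations
produce fewer false negatives. Evaluation is filtered mean rank (MR) over
head- and tail-prediction queries; completion scores every cross-type
entity pair under its best relation and keeps the top 10 % ·|train| unseen
pairs, measured by pooled Association Precision.

Everything — gradients included — is implemented in NumPy; analytic
gradients for every backbone × fusion combination are verified against
central finite differences in the test suite.

## Worked example

A built-in generator plants a typed knowledge graph whose triplets satisfy
`‖z_h + v_r − z_t‖ ≤ ε` in a hidden latent space, with category labels
naming each entity's latent module and description vectors that are noisy
linear images of the latent positions — so every stage runs offline with a
known ground truth.

```bash
kgfuse generate --entities 200 --relations 5 --triplet-count 2000 \
    --seed 1 --out demo/data
kgfuse train --triplets demo/data/triplets.tsv \
    --categories demo/data/categories.tsv \
    --backbone transh --fusion reverse-hp --lambda-c 0.2 \
    --k 16 --gamma 2.0 --epochs 100 --seed 1 --out demo/model.npz
kgfuse evaluate --model demo/model.npz --out demo/report.txt
```

The evaluation report:

```
queries	400
mean_rank	18.067500
mean_rank_predict_head	19.150000
mean_rank_predict_tail	16.985000
```

400 queries = two per held-out test triplet (predict the tail given the
head and relation, and vice versa). A mean filtered rank of 18 over 200
candidate entities means the correct answer typically lands in the top
decile; an untrained model sits near the uniform expectation of
(200+1)/2 ≈ 100.

Typed-pair completion then proposes new disease–gene links:

```bash
kgfuse infer --model demo/model.npz --head-type disease --tail-type gene \
    --out demo/edges.tsv
```

which writes the existent edges plus the 160 top-scored unseen pairs
(10 % of the 1600 training triplets), e.g.

```
disease-00032	gene-00003	2.683884	inferred
disease-00017	gene-00048	2.506290	inferred
disease-00152	gene-00138	2.189224	inferred
```

The library surface mirrors the CLI: `generate_synthetic_kg`, `split_kg`,
`fit`, `grid_search`, `entity_prediction_mr`, `infer_typed_pairs`,
`association_precision` — see the module docstrings.

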