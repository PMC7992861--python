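# Methods

## Problem and model

Disease-associated N7-methylguanosine (m⁷G) sites are expensive to confirm
experimentally, and the catalogue of validated site–disease links is sparse:
a few hundred links over hundreds of sites and diseases. `m7gnet` treats the
task as link prediction on a heterogeneous network. Three blocks are
combined into one symmetric adjacency matrix over the `m` sites followed by
the `n` diseases,

    A = [[A_SS, A_SD],        W = [[1,      W_SD],
         [A_SDᵀ, A_DD]],           [W_SDᵀ,  1  ]],

where `A_SS` is a site–site similarity network derived from the 41-bp
site-centered sequences, `A_DD` a disease–disease semantic similarity
network supplied as an input, and `A_SD` the binary association matrix. The
mask `W` marks observed entries: both similarity blocks are fully observed,
while in the site–disease block only the known (positive) associations are
observed. Unknown pairs are *unobserved*, not observed negatives — they
carry `A = 0` together with `W = 0`, so they exert no force on the fit and
can be scored afterwards.

The completion model assumes the association pattern is governed by a small
number `k ≪ m + n` of latent factors shared between similar sites and
similar diseases. Factors `U, V ∈ ℝ^{(m+n)×k}` are fitted by minimizing the
masked ridge-regularized loss

    L(U, V) = ‖W ⊙ (A − U Vᵀ)‖²_F + λ₁‖U‖²_F + λ₂‖V‖²_F,

and a candidate pair `(i, j)` is scored by the reconstruction `U Vᵀ` at the
site–disease block. Because the reconstruction of a symmetric `A` is not
itself exactly symmetric, the two cross blocks are averaged:
`score = ((UVᵀ)_{SD} + ((UVᵀ)_{DS})ᵀ) / 2`. Fusing the similarity blocks
into the completion problem is what lets a site with a single known disease
(or none in a test split) borrow strength from its sequence neighbours —
the usual cold-start failure of factorizing `A_SD` alone.

## Sequence features and similarity networks

Two encodings of each site-centered window are used.

* **Chemical (3 bits/base).** Each nucleotide is coded by (ring structure,
  hydrogen-bond strength, functional group): purines A,G carry a 1 in the
  first bit, the weakly pairing A,T in the second, the amino-bearing A,C in
  the third, giving A→(1,1,1), C→(0,0,1), G→(1,0,0), T→(0,1,0). A window of
  length L becomes a binary vector of length 3L and site pairs are compared
  with the Jaccard coefficient (positions where both are 1 over positions
  where either is 1). Every per-base code contains a 1, so the vectors are
  never all-zero and the coefficient is always defined.
* **CNF (cumulative nucleotide frequency).** Position `i` (1-based) carries
  `count(seq[i] within seq[1..i]) / i` — the running frequency of the
  occupying base within its prefix. The first entry is always 1, every entry
  lies in (0, 1], and the encoding is context-sensitive where the chemical
  code is purely per-base. CNF vectors are compared with the cosine
  coefficient, which for these nonnegative vectors lies in [0, 1].

The two site networks are fused per entry as
`(1 − α) · chemical + α · CNF` with `α ∈ [0, 1]`; `α = 0` and `α = 1`
recover the pure networks. Diagonals are forced to exactly 1 rather than
recomputed, and matrices are exactly symmetrized after the (symmetric by
construction) dense computation, to keep the downstream validators strict
(symmetry within 1e-10) without floating-point drift. Disease semantic
similarity (a DAG-based Wang-style phenotype measure) is consumed as a
precomputed matrix and only validated: square, symmetric within tolerance,
[0, 1], unit diagonal.

## Dataset construction rules

Site–variant records carry an association level in [0, 1] and a confidence
tier. The dataset filter keeps records at the required confidence tier
(default `high`) whose level is **strictly** above the threshold (default
0.8); a record at exactly 0.8 is excluded. Sequences are strictly
ACGT-alphabet; ambiguity codes are rejected rather than imputed, since both
encodings are undefined for them (RNA `U` can be opted into as `T`, off by
default). Duplicate (site, disease) pairs collapse to a single 1 with a
logged warning. Genomic coordinates are 1-based, strand-explicit metadata;
nothing downstream computes on them.

## ALS solver

With one factor fixed, `L` separates over the rows of the other factor, and
row `r` solves the ridge system

    (Σ_{c: W[r,c]=1} V_c V_cᵀ + λ₁ I) u_r = Σ_{c: W[r,c]=1} A[r,c] V_c.

The mask's block structure makes the observed column set of a site row “all
m sites plus this site's known diseases”, so the Gram matrix is a shared
site-block Gram plus a small per-row correction (symmetrically for disease
rows). This keeps a full sweep at `O((m+n)k² + (m+n)k·deg)` plus two
`(m+n)×k` matrix products, and a fit at study scale well under a second.

Choices:

* **Initialization** — `U, V` i.i.d. normal with standard deviation
  `1/√k`, seeded; this keeps the initial reconstruction O(1).
* **Stopping** — relative loss change `< tol` (default 1e-6) or `max_iter`
  (default 200) sweeps; hitting the cap flags `converged_ = False` and logs
  a warning rather than raising.
* **Monotonicity** — each half-sweep solves its subproblem exactly, so the
  loss is non-increasing across sweeps; the test suite asserts this on every
  fit it makes. The problem is non-convex, so the fixed point is a local
  minimum that depends on the seed; runs are reproducible given
  (config, seed).
* **Degeneracy** — `λ₁, λ₂ > 0` is enforced, which keeps every row system
  non-singular regardless of the mask.
* **Recovery convention** — on fully observed low-rank matrices with
  `k = rank`, recovery is measured as *relative* Frobenius error, the
  standard convention; with any nonzero ridge an absolute-error reading is
  bounded away from zero by the shrinkage bias.

Default hyperparameters are `k = 90` and `λ₁ = λ₂ = 2⁻² = 0.25` (the grid
`{2⁻², …, 2²}` is searched as actual values), and `α` defaults to 1 —
CNF-only similarity, the encoding that carries sequence context rather than
per-base identity. On the synthetic study dataset the latent rank is known,
so tests use `k` equal to the planted rank.

## Evaluation protocols

* **Repeated 10-fold CV** — known positives are shuffled (per-repeat seed
  derived from the master seed), split into folds; each fold is hidden with
  `mask_out` (both `A` and `W` entries zeroed at both symmetric positions,
  so no leakage path exists), the model refitted, and the hidden positives
  ranked against the scores of *all* never-known pairs from the same fit.
  One AUC per fold, averaged per repeat; mean ± sd across repeats.
* **Global LOOCV** — each known pair hidden alone and ranked against all
  never-known pairs.
* **Local LOOCV** — candidates restricted to the held-out pair's disease
  column; a disease with no unknown pairs is skipped with a warning. The
  per-pair rank statistics are averaged rather than pooled, which keeps
  diseases with differently sized candidate pools on an equal footing.

AUC is the Mann–Whitney statistic (ties count ½), computed from ranks; it
equals the area under the ROC curve swept by a rank threshold and is
invariant under monotone transforms of the scores. A harness-internal
assertion checks, for every CV iteration, that the test pairs are absent
from both `A` and `W` of the fitted network.

Grid search evaluates k-fold CV on the product of the `k`, `λ` and `α`
grids (by default `λ₁ = λ₂`; the untied product is available), returning
the full table and the argmax; this supports the two-stage procedure of
fixing `α` while searching `k`/`λ`, then sweeping `α` at the best `k`/`λ`.

## Synthetic data generator

The generator makes the model's core assumption true by construction so
that parameter recovery is a meaningful test:

* sites and diseases are assigned to `true_rank` latent groups; latent
  factors are one-hot group indicators plus N(0, 0.2²) jitter;
* disease factor rows are scaled by lognormal(0, 0.8) prevalence weights,
  so known links concentrate on a few diseases — the strong per-disease
  skew characteristic of real association databases. This heterogeneity is
  also what gives local LOOCV its bite: global LOOCV benefits from
  between-disease score differences that cancel within a disease column;
* association scores are `P Qᵀ` plus N(0, noise_sd²) noise (default 0.1),
  and the top `n_known` scores (default 80 over a 60 × 20 grid) become the
  known associations. A uniform-random mode severs the associations from
  all structure for null calibration;
* sequences are per-group archetype 41-mers copied with 15% per-position
  mutation (center base fixed to G, honouring the site-centered
  convention), so the sequence-derived similarity networks genuinely carry
  the group signal; disease similarity comes from normalized inner products
  of group-correlated nonnegative profiles.

Default sizes (m = 60, n = 20, rank 4, 80 known pairs) keep a full
10-fold CV in seconds and full double LOOCV under a minute on one core; the
test suite runs all its protocols at these sizes.

What the generator does **not** emulate: real sequence composition around
m⁷G sites (motifs, GC skew), ontology-derived disease similarity structure,
biased discovery of associations (ascertainment), or any relation between a
site's variant metadata and its linkable diseases. Passing tests therefore
demonstrate that the pipeline recovers a plantable low-rank signal routed
through its own similarity channels — not that the biological signal in any
particular real dataset is of this form or strength.

## Known limitations

* The factorization objective is non-convex; only local convergence is
  guaranteed (or claimed), and different seeds can reach different optima.
  CV reports therefore always record the master seed.
* Observed-positive-only masking cannot use verified negatives if any
  existed.
* LOOCV refits once per known association; at hundreds of positives and
  `k ≈ 90` this is minutes of compute, the price of the protocol rather
  than of the implementation.
* Disease semantic similarity is trusted as given apart from structural
  validation; no attempt is made to recompute or audit it.
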