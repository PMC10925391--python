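# Methods

## Diffusion core

The generator is a variance-exploding (VE) diffusion model: forward SDE
`dx = g(t) dw` with `g(t)² = dσ²(t)/dt` and geometric schedule
`σ(t) = σ_min^(1−t) · σ_max^t` on normalized time `t ∈ [0, 1]`. The
transition kernel is Gaussian, `p_0t(x_t|x_0) = N(x_0, σ(t)² I)`, giving the
conditional score `−(x_t − x_0)/σ(t)²` used as the DSM regression target.
Time is sampled uniformly.

The score network is a two-hidden-layer tanh MLP (numpy, hand-written
backprop, Adam) over `[x, time-embedding, context]`. It predicts scaled
noise: `s_θ = net(·)/σ(t)`, keeping the regression target O(1) at every
noise level. The final layer is zero-initialized so the untrained score is
exactly zero.

**DSM weighting.** The default plain-training weight is `λ(t) = σ(t)²`
(the standard VE choice; for this SDE it is also likelihood weighting up to
a constant, since `g(t)² ∝ σ(t)²`). Under the noise-prediction
parametrization the per-sample loss scales as `1/σ(t)²`, so this weight
gives every noise level an equal effective contribution.

**Sampler.** Euler–Maruyama on a uniform time grid from the prior
`N(0, σ_max² I)`, default 20 steps; the last step injects no noise (pure
denoise). Left-endpoint discretization has a small O(Δt) variance bias
(~0.3% in std at 100 steps), below the resolution of the KS checks used in
the tests; two alternative discretizations (exact variance increments, and
NCSN-style ancestral steps) were evaluated and are *worse* calibrated for
broad data distributions, so plain EM is kept. VE sampling is accurate only
when `σ_max` clearly exceeds the data scale: the prior-mismatch error of
the mean contracts by `(σ_0² + σ_min²)/(σ_0² + σ_max²)`, which is why
distributional tests use `σ_max = 20` for unit-scale data and the docking
task uses `σ_max = 16` for poses in a ±6 box.

A wrapped-normal torus variant (5-term wrapping) is provided in
`confboot.torus` for completeness; the Euclidean space is the default
everywhere.

## Synthetic docking task

The task is a deliberately minimal analogue of blind docking across protein
domain clusters, in R² by default:

- a **cluster** (≙ binding-domain cluster) has 3 pocket centers, uniform in
  a ±6 box, pairwise ≥ 4 units apart, each with a unit "chemistry" vector
  u_j, plus a cluster compatibility frame (rotation R_ω);
- a **complex** pairs a unit ligand feature ℓ with a cluster; the correct
  pocket is `argmax_j ⟨u_j, R_ω ℓ⟩` and the true pose sits within 1 unit of
  its center (Gaussian offset, σ = 0.35);
- the **context** d — everything a docking method may see — concatenates ℓ,
  all pocket (center, chemistry) pairs and the frame; never the pose;
- **held-out clusters** draw chemistry angles and frames from the angular
  region disjoint from the training clusters' region, so the generator must
  extrapolate, and their pocket centers keep a 3-unit margin from every
  training-cluster center, so a held-out pose can never be "solved" by
  reproducing a training pocket;
- the success threshold is 2 distance units, mirroring the 2 Å convention;
  with pockets ≥ 4 apart a wrong-pocket pose is an unambiguous failure.

Defaults: 4 training clusters, 2 held-out, 10 complexes each (held-out
clusters always ≥ 6 complexes).

**What the task does not emulate:** molecular geometry, chemistry-aware
ligands, receptor flexibility, pose symmetry. Passing results show that the
*training mechanism* works — confidence feedback can redirect a diffusion
generator on contexts it cannot solve zero-shot — not that it works on real
protein structures.

## Pretraining and the generalization gap

The generator is pretrained by plain DSM on the training clusters' (pose,
context) pairs (3000 Adam steps, batch 64, lr 1e-3). Pretraining uses **20%
context dropout**: without it the small MLP extrapolates to held-out
contexts as a confidently wrong point mass (sample spread ≈ 0.5 units),
leaving rollouts with nothing for the confidence model to select; with it
the model retains a broad multimodal unconditional component (spread ≈ 3–8
units on unseen clusters), the toy analogue of the diverse pose samples a
docking diffusion model produces on new proteins. On the default task the
pretrained model solves its training clusters essentially perfectly and
0–25% of held-out complexes — the generalization gap the method closes.

## Confidence models

- **Oracle:** `c(x) = τ − ‖x − x*‖` with τ = 2 — positive iff the pose is a
  success; used in the upper-bound ablation.
- **Learned:** logistic regression on *relative* check features computed
  from the public context only: per pocket (ordered by ligand
  compatibility) the compatibility `⟨u_j, R_ω ℓ⟩`, the pose–center distance
  and a hinge `max(0, τ − dist)`, plus the distance to the most compatible
  pocket and the minimum distance. Checking is local in these coordinates,
  which is exactly why the classifier transfers across clusters (held-out
  AUROC > 0.95) while the generator does not — the package's concrete
  instantiation of "it is easier to check a pose than to generate one".
  Training data come from training clusters only: generator rollouts plus
  kernel-perturbed true poses at several radii (so both classes are always
  populated), labelled by `1{‖x − x*‖ < τ}`. The confidence model is frozen
  during bootstrapping.

## The bootstrapping loop

Per iteration: roll out 8 poses per target complex, score them, then 50
Adam steps on batches of 32 — half real training pairs, half buffer draws
resampled with replacement ∝ `exp(c/temperature)` (temperature 1; the
softmax over a fully separated logistic logit is nearly an argmax, which is
the literal `exp[c]` rule). The buffer is rebuilt from fresh rollouts each
iteration (`reset`; `accumulate` is available). K = 30 iterations by
default.

**Time weighting.** `λ(t) = (1−t)·σ(t)²` for the real half and
`λ′(t) = t·σ(t)²` for the buffer half. In effective (variance-normalized)
units these are linear ramps `(1−t)` and `t`: real data dominate the fine
small-t denoising steps, buffer feedback dominates the coarse large-t steps
where the pocket is chosen. The σ² factor matters: without it essentially
all gradient signal lands at t ≈ 0 and the buffer term cannot steer the
pocket choice (empirically the unnormalized ramps still improve held-out
success, but by half as much). The two profiles cross at exactly t = 1/2.

**Protocol.** Following the study design, fine-tuning runs *per held-out
cluster* (one model copy each, fresh Adam state); aggregate metrics weight
clusters by complex count. Evaluation per iteration: 8 samples per complex,
top-1 by the learned confidence (also when the oracle drives the feedback,
so ablations differ only in the feedback signal), success rate and median
top-1 distance. Training and evaluation consume independent RNG streams, so
the learning trajectory is bit-identical whether or not evaluation runs —
this is also how the no-label-leakage test works.

Typical behavior over seeds 0–8: held-out top-1 success rises from 0–25% to
25–100% (mean gain ≈ +50 points); median buffer confidence rises in most
runs (the Fig-4A-style signature); the oracle-driven variant is at least as
good as the learned one; an anti-correlated confidence (−oracle) collapses
the generator onto wrong pockets and never beats its baseline — feedback
quality, not the loop itself, is what creates improvement.

## Van der Mer extraction

A candidate sidechain's contacts are residues with ≥ 1 heavy atom within
4.5 Å of the candidate's sidechain heavy atoms (Cβ onward), restricted to
sequence separation ≥ 7 on the same chain (other chains always count).
Candidates need ≥ 4 contacts by default; excision removes the candidate ±2
sequence neighbors from the receptor; the pocket is the contact set
restricted to surviving residues. All four thresholds are exposed
(`dist_cutoff`, `min_seq_sep`, `min_contacts`, `window`) and carry
literature-standard defaults. Highest-occupancy altlocs are kept;
non-standard residues are skipped as candidates but count as contacts; the
ligand excludes backbone atoms (option `include_ca`). Output: receptor PDB,
ligand PDB + SDF (single bonds perceived from covalent distances at 1.3×
summed covalent radii), pocket TSV. The test fixture generator produces
random compact chains (CA random walk confined to a sphere with template
sidechains) — parseable, geometrically plausible, *not* physically valid
protein structures, and labelled synthetic.

## Curation and metrics

Curation acts on pre-built record tables: drop complexes sharing a pocket
with another ligand, metals, crystal additives, ligands with > 60 heavy
atoms; then keep at most 5 complexes per ligand identity (smallest complex
ids first — the tie-break is this package's choice). Cluster splitting is a
seeded half/half partition at cluster level. RMSD is heavy-atom,
holo-frame, no re-superposition, and ignores graph automorphisms (ring
flips count as deviations — a documented simplification). Binding-site
similarity: per residue pair `s(x,y)/√(s(x,x)s(y,y))` under BLOSUM62,
clipped to [0,1]; best-match average in each direction; harmonic mean of
the two directions. Identical sites score exactly 1; the measure is
symmetric and bounded in [0,1].

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.Generator` seeds; identical
  seeds give identical tasks, models, rollouts and histories.
- `sigma_of_t` rejects t outside [0,1]; `K = 0` returns the input model
  unchanged; empty batches/buffers and single-class confidence training
  sets raise `ValueError`; non-finite scores abort sampling with the
  offending time and context.
- Buffer capacity (10 000) evicts oldest entries first; irrelevant under
  the `reset` policy at default sizes.
- Candidate ordering breaks contact-count ties by (chain, index, insertion
  code) for byte-stable outputs.

## Known limitations

- The pose space is low-dimensional Euclidean; no SE(3) equivariance,
  torsion products, or protein encoders.
- The learned confidence uses engineered relative features rather than a
  learned representation; its transfer ability is partly built in by
  design, which is the intended premise, not a discovery.
- Global `exp(c)` buffer resampling concentrates updates on the currently
  best-scoring complexes; clusters whose rollouts never approach a correct
  pocket may not improve (also observed at full scale).
- The EM sampler's small variance bias would matter for much tighter
  distributional tolerances than used here.
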