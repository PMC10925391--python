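# confboot

Self-training for score-based docking generators: a complete, desk-scale
implementation of **confidence bootstrapping** — fine-tuning a diffusion
generator on protein targets *without structural labels*, using only the
feedback of a frozen confidence model — together with the two companion
tools such a study needs: **van der Mer synthetic-complex extraction** from
crystal structures, and **domain-cluster-disjoint benchmark curation** with
standard pose metrics.

## Who this is for

Researchers studying generalization of ML docking methods: how a generative
pose model trained on one set of binding-domain clusters can be pushed to
work on unseen clusters, exploiting the observation that *checking* a pose
is easier than *generating* one. Everything runs in minutes on one CPU on a
synthetic blind-docking analogue, so the training dynamics themselves — not
protein engineering — are the object of study.

## The method

A variance-exploding diffusion model with geometric noise schedule
σ(t) = σ_min^(1−t) σ_max^t learns a conditional score s_θ(x, t; d) of poses
x given complex context d by denoising score matching:

    L(θ) = E_{t~U[0,1]} λ(t) E_{x0,d} E_{x_t|x0} ‖ s_θ(x_t, t; d) − ∇ log p_0t(x_t|x0) ‖²

with the Gaussian transition kernel p_0t = N(x0, σ(t)² I). A confidence
model c_φ(x, d) scores how likely a pose is correct.

Confidence bootstrapping runs K iterations of:

1. **rollout** — sample poses for the target complexes (contexts only; true
   poses are never read) by reverse diffusion from the current θ_i;
2. **scoring** — annotate every pose with c_φ, forming a buffer B;
3. **update** — a fixed number of SGD steps on a two-term score-matching
   objective: real training complexes weighted by λ(t) (emphasis on small t,
   preserving fine denoising) and buffer poses resampled with probability
   ∝ exp[c_φ(x,d)] weighted by λ′(t) (emphasis on large t, steering the
   coarse pocket choice).

Only θ moves; the confidence model stays frozen. Evaluation follows the
standard top-1 protocol: 8 samples per complex, ranked by confidence,
success = top-1 within 2 distance units of the true pose.

## Worked example

```bash
confboot make-task --seed 0 --out task/
confboot bootstrap --task task/ --seed 0 --out run/
```

generates the default synthetic study (4 training clusters, 2 held-out
clusters, 10 complexes each; every cluster has ≥ 3 pockets spaced ≥ 4 units
apart) and prints:

```json
{
  "seed": 0,
  "confidence": "learned",
  "baseline_success": 0.15,
  "final_success": 0.35,
  "baseline_median_distance": 6.30,
  "final_median_distance": 5.95
}
```

meaning: the pretrained generator docks 15% of held-out complexes correctly
(top-1 within 2 units); after 30 bootstrapping iterations driven purely by
the learned confidence model — which never sees a held-out pose — top-1
success rises to 35%. `run/history.tsv` traces, per iteration, the median
buffer confidence and the per-cluster success rates, e.g.

```
iteration  median_confidence  success_rate  cluster4_success  cluster5_success
0          -27.72             0.30          0.3               0.3
29         -10.78             0.35          0.4               0.3
```

The rising median confidence is the signature of the method: the generator
is being pulled toward the regions the confidence model trusts. Averaged
over several seeds the gain is larger (typically +40 to +60 points); some
clusters never improve, matching the behavior of the full-scale method on
clusters where the initial model has no signal.

Other entry points:

```bash
confboot vdm-extract --pdb structure.pdb --min-contacts 4 --out vdm/   # synthetic complexes
confboot curate --records records.tsv --seed 0 --out curated/          # benchmark filtering + split
confboot evaluate --pred pred.tsv --truth truth.tsv --report out.tsv   # top-1 RMSD report
```

As a library: `confboot.pipeline.bootstrap_experiment(seed=0)` runs the
whole study in one call, and each stage (`diffusion`, `toytask`,
`confidence`, `bootstrap`, `vdm`, `dockgen`) is importable on its own.

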