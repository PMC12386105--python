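# mircoop

Knowledge-enhanced miRNA cooperation-network construction and module
biomarker discovery for two-group expression studies.

## The problem

Case/control miRNA expression studies typically have a few dozen samples
and a few hundred mature miRNAs. Single-marker statistics miss miRNAs
that act jointly, and purely data-driven networks built at such sample
sizes are riddled with false-positive links. `mircoop` addresses both:
it finds *module biomarkers* — small sets of cooperating miRNAs that
jointly separate the groups — and uses curated miRNA–disease association
knowledge to denoise the data-driven network before module search.

## The method

Given expression values for features `F = {f_1..f_m}` on `n` labeled
samples and a binary disease-association profile `d(f_i)` per miRNA, the
pipeline has three stages:

1. **Cooperation network.** For each pair `(f_i, f_j)` a linear
   soft-margin SVM gives the hyperplane `α_ij f_i + β_ij f_j + γ_ij = 0`;
   the combinatorial feature `f_com = α_ij f_i + β_ij f_j + γ_ij` is
   tested for a group difference with a two-sample t-test, and an edge is
   drawn iff `p < 0.05`. Node attributes are `x(f_i) = [d(f_i) ‖ s(f_i)]`
   (knowledge concatenated with the expression profile).

2. **Graph auto-encoder enhancement.** A two-layer graph-convolution
   encoder `Z = Â · ELU(Â X W₀) · W₁` (with `Â` the symmetrically
   normalized adjacency with self-loops) and an inner-product decoder
   `sigmoid(Z Zᵀ)` are trained under

   `L_total = L_rec + λ₁·L_fc + λ₂·L_mp`

   where `L_rec` is the (negative-sampled) MSE between adjacency and
   reconstruction, `L_fc = ‖GS − GS′‖²_F` ties the Gaussian
   interaction-profile (GIP) kernel of the latent rows to the GIP kernel
   of the disease profiles, and `L_mp` is a supervised-contrastive term
   (temperature τ) on a linear discriminator head that separates
   differentially from non-differentially expressed miRNAs
   (pseudo-labels from per-feature t-tests). The enhanced network keeps
   the cooperation edges whose decoder probability is ≥ θ, reweighted by
   that probability.

3. **Module search and voting.** Starting from the node with the
   largest weighted degree, modules grow greedily along the heaviest
   outgoing edge; a candidate that does not improve the module's
   cross-validated AUC is still accepted with probability
   `Prob_t = 1 − exp((AUC_cmn − 1)/cmn)`. Found modules are removed and
   the search repeats. The top-k modules by AUC each train a
   standardized linear SVM; samples are classified by majority vote.

Everything is implemented in numpy/scipy/scikit-learn; the auto-encoder
uses hand-derived analytic gradients (verified against finite
differences in the test suite) and Adam, so every run is exactly
reproducible from a seed.

## Worked example

The built-in generator plants three modules of 8 correlated,
differentially expressed miRNAs (ρ = 0.6, case shift δ = 1.5) among 120
features on 30 + 30 samples, together with a knowledge table whose rows
agree within modules up to 5% flip noise:

```python
from mircoop import RunConfig, SimulationSpec, simulate, run_pipeline

data, knowledge, truth = simulate(SimulationSpec(seed=0))
config = RunConfig(seed=0)
modules, ensemble, artifacts = run_pipeline(data, knowledge, config)

coop = artifacts["cooperation_network"].graph
enhanced = artifacts["enhanced_network"]
print(f"cooperation network: {coop.n_edges()} edges over {coop.n_nodes} miRNAs")
print(f"enhanced network:    {enhanced.n_edges()} edges kept after auto-encoder pruning")
for i, (members, auc) in enumerate(modules.modules, 1):
    print(f"M_{i}: AUC = {auc:.3f}, size = {len(members)}")
```

prints

```
cooperation network: 3482 edges over 120 miRNAs
enhanced network:    2054 edges kept after auto-encoder pruning
M_1: AUC = 0.997, size = 7
M_2: AUC = 0.990, size = 8
M_3: AUC = 0.977, size = 8
M_4: AUC = 0.972, size = 3
M_5: AUC = 0.971, size = 4
M_6: AUC = 0.964, size = 3
M_7: AUC = 0.883, size = 1
```

The pairwise fit-then-test edge rule links almost half of all pairs at
this sample size; the auto-encoder prunes ~40% of them, preferentially
dropping links to non-differential background miRNAs. The seven selected
modules (cross-validated AUC ≥ 0.88) then vote: held-out accuracy on
samples never seen by any stage is 90–98% across seeds.

A `mircoop` command-line interface exposes each stage
(`simulate | preprocess | build-net | enhance | find-modules | run |
predict | evaluate`); see `mircoop --help`.

## Layout

- `src/mircoop/io.py` — validated containers and TSV/edge-list/GMT I/O
- `src/mircoop/preprocess.py` — probe collapse onto miRNA accessions
- `src/mircoop/coop.py` — pairwise-SVM cooperation network
- `src/mircoop/gae.py` — graph auto-encoder, losses, training
- `src/mircoop/modules.py` — greedy module search, voting ensemble
- `src/mircoop/synthetic.py` — planted-module benchmark generator
- `src/mircoop/pipeline.py` — orchestration, repeated cross-validation
- `docs/methods.md` — model details, parameter choices, limitations
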