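# dynmod

Dynamic network-reconfiguration analysis for block-design working-memory
fMRI: HRF-weighted functional connectivity, static and multilayer
modularity, and module-allegiance cartography, with signal-detection
behavioral scoring and a ground-truth synthetic-data generator.

## What it is for

Training on a demanding task (e.g., a dual n-back working-memory task
practiced over weeks) reorganizes the brain's functional network: as
performance automates, whole-brain modularity rises and the interplay of
large-scale systems (frontoparietal, default mode, subcortical, ...)
shifts between segregation and integration. `dynmod` provides the
network side of that analysis for anyone with ROI time series from an
alternating block design:

- **connectivity** — per-condition and per-block weighted Pearson
  correlation matrices, with task boxcars convolved with a canonical HRF
  supplying the volume weights; Fisher z-transform; positive edges only;
- **static_community** — Newman–Girvan modularity
  `Q = (1/2μ) Σᵢⱼ (Aᵢⱼ − γ kᵢkⱼ/2m) δ(gᵢ,gⱼ)`, Louvain-style
  optimization (best of 100 seeded restarts), normalized by the mean Q of
  degree-preserving rewired null networks;
- **multilayer_community** — generalized Louvain on the supra-graph of
  task-block layers with condition-dependent interslice coupling
  (ω = 1 same condition, 0.5 different), quality
  `Q_ML = (1/2μ) Σᵢⱼₛᵣ [(Aᵢⱼₛ − γₛVᵢⱼₛ)δₛᵣ + δᵢⱼωₛᵣ] δ(g_{is},g_{jr})`;
- **cartography** — module-allegiance matrix `P` (fraction of
  optimization × layer instances co-assigning two nodes), system
  recruitment `R_S = (1/n_S²) Σ_{i,j∈S} P_{ij}` and pairwise integration
  `I_{kl} = (1/n_k n_l) Σ_{i∈S_k, j∈S_l} P_{ij}`, normalized by a
  label-permutation null that removes system-size bias;
- **behavior** — d′ = Z(H) − Z(F) per subject × session × condition ×
  modality, with endpoint clamping (0 → 0.01, 1 → 0.99) and cross-session
  percent-improvement summaries;
- **synthgen** — synthetic ROI panels with planted, block-varying
  community structure (compound-symmetric within/between-module
  correlations) and Bernoulli trial outcomes, so every stage above can be
  validated against known ground truth;
- **pipeline / CLI** — a config-driven study runner
  (`dynmod run-all --config study.yaml`) plus subcommands `simulate`,
  `connectivity`, `communities`, `cartography`, `behavior`, `contrasts`.

Community detection is exposed sklearn-style
(`LouvainCommunities`, `MultilayerCommunities`: `fit`, `labels_` /
`assignment_`, `get_params`) and composes with sklearn tooling; the
module-level functions are thin wrappers.

## Worked example

Plant a 60-node network with four systems in which `sys0` keeps its
module in every block while half of `sys3` defects into `sys1`'s module
on alternating blocks, then run the full dynamic analysis:

```python
import dynmod as dm
from dynmod.synthgen import (ScenarioSpec, SystemAtlas,
                             stable_splitting_partitions)
from dynmod.multilayer_community import MultilayerNetwork

atlas = SystemAtlas.equal_systems(60, 4)
parts = stable_splitting_partitions(atlas, 20, "sys0", "sys3")
spec = ScenarioSpec(n_nodes=60, atlas=atlas, planted_partitions=parts,
                    rho_within=0.6, rho_between=0.05, noise_sd=0.0,
                    n_blocks=20, samples_per_block=15, seed=42)
panel = dm.generate_panel(spec)

A = dm.condition_connectivity(panel, None)          # session-level graph
res = dm.normalized_modularity(A, n_runs=100, n_null=20, seed=0)
print(f"static modularity Q = {res.Q:.3f}, "
      f"normalized Q = {res.Q_normalized:.3f} ({res.n_modules} modules)")

stack = dm.block_connectivity(panel)                # 20 layer matrices
ensemble = dm.run_ensemble(MultilayerNetwork.from_stack(stack),
                           n_opt=50, seed=0)
P = dm.allegiance(ensemble)
carto = dm.permutation_normalize(P, atlas, n_perm=500, seed=0)
for system in ("sys0", "sys3"):
    print(f"normalized recruitment {system}: "
          f"{carto.value('recruitment', system):.3f}")
print(f"normalized integration sys1|sys3: "
      f"{carto.value('integration', 'sys1', 'sys3'):.3f}")
```

Output:

```
static modularity Q = 0.460, normalized Q = 3.540 (3 modules)
normalized recruitment sys0: 3.011
normalized recruitment sys3: 2.280
normalized integration sys1|sys3: 1.752
```

Read: the session network is ~3.5× more modular than its rewired nulls;
the stable system recruits more strongly than the splitting one
(3.01 vs 2.28 — its nodes stay together across optimizations and
blocks), and the splitting system's above-chance integration with its
merge target (1.75 > 1) reflects exactly the planted defection.

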