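# strucnet

Group analysis of structural brain connectomes built from deterministic
tractography. The package is aimed at researchers comparing two cohorts
(e.g. a patient group against matched controls) on whole-brain networks
whose nodes are parcellated gray-matter regions and whose edge weights
are streamline counts (NOS, number of streamlines), and at methodologists
who need a fully synthetic, self-contained test bed for such pipelines.

## What it computes

**Graph construction.** Each subject contributes a symmetric, nonnegative
integer N×N NOS matrix over a fixed 83-node schema (68 Desikan–Killiany
cortical regions, 14 subcortical structures, brainstem). Edges with NOS
< 2 are pruned as spurious; a two-step group threshold then keeps only
edges present (nonzero) in at least τ = 60% of each group's members and
subsequently in ≥ 60% of the pooled sample, with a 30–90% stability sweep
in 5% steps.

**Network-based statistic (NBS).** For each kept edge a pooled-variance
two-sample t statistic is computed (df = n₁ + n₂ − 2). Edges exceeding
the primary threshold (the one-sided t quantile at p < 0.01) form a
suprathreshold graph whose connected components, sized by edge count,
are the candidate effects. Shuffling group labels K = 5000 times and
recording the maximum component size per shuffle yields the null
distribution; a component of size s receives

  p_FWER = (1 + #{k : max-size(k) ≥ s}) / (1 + K),

which controls the family-wise error rate at the component level.

**Weighted graph metrics.** Nodal strength sᵢ = Σⱼ wᵢⱼ; the Onnela
weighted clustering coefficient Cᵢ = (kᵢ(kᵢ−1))⁻¹ Σⱼₕ (ŵᵢⱼ ŵᵢₕ ŵⱼₕ)^⅓
with ŵ = w/max(w); shortest weighted path lengths under the 1/w length
transform; global strength and total fiber count (which satisfy
total = strength·N/2 exactly). Small-world indices γ and λ divide the
observed global clustering and characteristic path length by their means
over 1000 degree-matched random networks obtained by Maslov–Sneppen
double-edge swaps in which weights travel with edges. Group differences
are tested with 10 000-permutation mean-difference tests and
Benjamini–Hochberg FDR within each metric family.

**Tractography.** A voxel-grid FACT tracker (8 seeds per white-matter
voxel, bidirectional propagation along the tensor's principal
eigenvector, termination at FA < 0.1, turning angle > 45°, or mask exit)
plus a log-linear tensor fit, validated on synthetic phantoms.

**Synthetic cohorts.** `strucnet.synth` generates two-group cohorts at
the reference design — 41 cases vs 42 controls over 83 nodes, ~25% edge
density, lognormal edge means in the tens-to-hundreds of streamlines,
subject-level coefficient of variation 0.5 — with an optional deficit
(default: 37% reduction on a 7-edge left-hemisphere orbitofrontal–
striatal–temporo-limbic subnetwork) planted in the case group.

## Worked example

```python
import strucnet as sn
from strucnet.synth import default_effect_edges

target = default_effect_edges(sn.generic_schema(83))
spec = sn.CohortSpec(seed=3, effect=sn.EffectSpec(target, reduction=0.37))
study = sn.sample_cohort(spec)                       # 41 vs 42 subjects
pruned = sn.GroupStudy(
    group_a=[sn.prune_spurious(c) for c in study.group_a],
    group_b=[sn.prune_spurious(c) for c in study.group_b],
)
masked, mask = sn.group_threshold(pruned)            # two-step 60%
res = sn.nbs_test(masked, mask, n_perm=1000, seed=4)
print(mask.n_edges, sn.density(mask))
print([(c.size, round(c.p_fwer, 4)) for c in res.components[:3]])
```

prints

```
865 0.25418748163385246
[(7, 0.004), (1, 1.0), (1, 1.0)]
```

865 of the 3403 possible edges survive the group threshold (density
0.254). The NBS finds one 7-edge component at p_FWER = 0.004 — exactly
the planted subnetwork (edge Jaccard 1.0 against `target` on this seed)
— while the remaining single-edge components are clearly null. A
connectome from the same cohort normalizes to γ ≈ 1.9 and λ ≈ 1.04
against its degree-matched ensemble, the small-world regime expected of
structural brain networks.

The same flow is scriptable end to end:

```bash
strucnet simulate cohort --out cohort/ --seed 3
strucnet pipeline run --config config.yaml
```

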