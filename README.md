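# swallownet

Graph-theoretical analysis of brain functional networks during voluntary
saliva swallowing.

Swallowing recruits a distributed set of cortical and subcortical regions
(sensorimotor cortex, supplementary motor area, insula, cingulate cortex,
basal ganglia, thalamus, …), and dysphagia after stroke or neurodegeneration
makes the network organization of these regions clinically relevant.
`swallownet` implements the full connectivity analysis for this setting:
from per-subject regional fMRI time series to partial-correlation
connectivity matrices, thresholded binary and weighted networks, graph
measures, degree-matched null ensembles, small-world and hierarchy
statistics, and the statistical comparison of swallowing-related regions
against the whole brain.  Because task fMRI cohorts of this kind are rarely
shareable, the package also ships a synthetic cohort generator that
reproduces the statistical structure of such data (local intra-hemispheric
correlation blocks, strong homologous inter-hemispheric correlations, AR(1)
temporal autocorrelation), so the entire pipeline is testable end to end.

## The analysis

Nodes are the 90 cerebral regions of the AAL parcellation (45 per
hemisphere; packaged as a CSV table together with the 42 swallowing-related
ROI flags).  For each subject:

1. **QC and preparation.** The first 10 volumes are discarded for magnetic
   equilibration (350 → 340 time points).  Head motion is summarized as the
   mean frame-to-frame displacement
   `(1/(M−1)) Σᵢ √(Δxᵢ² + Δyᵢ² + Δzᵢ²)` for translations (mm) and rotations
   (degrees); subjects with any frame displacement > 4.0 mm are excluded.
2. **Connectivity.** Entry (i, j) is the *partial correlation* between
   regions i and j controlling for the other 88 regions, computed from the
   precision matrix P = R⁻¹ of the sample correlation R as
   `−P_ij / √(P_ii P_jj)`.
3. **Network construction.** Either the matrix is thresholded to a target
   mean degree K (default K = 48, i.e. exactly K·90/2 = 2160 edges,
   retaining the largest |connectivity| values), or binarized over a
   sparsity-threshold sweep r = 0, 0.05, …, 1.  Weighted networks carry the
   retained magnitudes normalized to (0, 1].
4. **Graph measures.** Degree k, clustering coefficient C (binary triangle
   fraction; weighted geometric-mean variant), shortest paths (weighted
   edge length 1/w), characteristic path length Lp (harmonic-mean form,
   finite on disconnected graphs, or arithmetic), global efficiency
   E_glob = ⟨1/d_ij⟩, local efficiency E_loc (efficiency of each node's
   neighbor subgraph), and the hierarchy exponent β of C(k) ∝ k^(−β).
5. **Null models and small-worldness.** 1000 (configurable) degree-matched
   random networks per subject via Markov-chain double-edge swaps;
   γ = Cp/C_rand, λ = Lp/L_rand, σ = γ/λ, with σ > 1 and γ > 1 indicating a
   small-world topology.
6. **ROI vs whole brain.** All measures are computed per subject and per
   sweep threshold for the whole brain and for the swallowing-ROI
   submatrix, and compared with the two-sided Mann–Whitney rank-sum test
   (exact enumeration for small tie-free samples).

## Worked example

```python
import swallownet as sn

# simulate a small cohort with the study's regional structure
spec = sn.CohortSpec(n_subjects=4, seed=7)
cohort = sn.generate_cohort(spec)

matrices = []
for ts, motion in cohort:
    if sn.qc_exclude(motion):                 # 4.0 mm head-motion rule
        continue
    ts = sn.discard_initial_volumes(ts, 10)   # 350 -> 340 volumes
    matrices.append(sn.partial_correlation(ts))

binary, weighted = sn.threshold_to_mean_degree(matrices[0], K=48)
summary = sn.network_summary(binary)
print(f"edges={binary.n_edges}  K={summary.K_mean:.1f}  "
      f"Cp={summary.Cp:.3f}  Lp={summary.Lp:.3f}  "
      f"Eglob={summary.Eglob:.3f}  Eloc={summary.Eloc:.3f}")

ens = sn.null_ensemble(binary, n_random=100, seed=0)
sw = sn.small_worldness(summary, ens)
print(f"gamma={sw.gamma:.3f}  lambda={sw.lam:.3f}  sigma={sw.sigma:.3f}")
```

prints

```
edges=2160  K=48.0  Cp=0.570  Lp=1.299  Eglob=0.770  Eloc=0.785
gamma=1.032  lambda=1.000  sigma=1.032
```

Exactly 2160 edges survive the K = 48 threshold, giving mean degree 48.
The network's clustering (0.570) slightly exceeds the degree-matched null
expectation (γ = 1.032) while its harmonic path length equals the null's
(λ = 1.000): at this conservative density the planted modular structure
leaves the network marginally small-world (σ > 1).  Sparser thresholds
(smaller K or larger r) sharpen the contrast.

The command line mirrors the stages:

```bash
swallownet simulate --out-dir cohort --subjects 22 --seed 1
swallownet connectivity cohort/sub-*_series.tsv --out-dir conn
swallownet threshold conn/sub-01_pcorr.tsv --mean-degree 48 --out-prefix net
swallownet nulls net_binary.tsv --n-random 1000 --seed 1
swallownet run-all --out-dir run --seed 1        # everything at once
swallownet export-atlas --out aal90.csv
```

## Layout

- `src/swallownet/atlas.py` — packaged 90-region table and swallowing-ROI set
- `src/swallownet/synthetic.py` — cohort generator and planted ground truth
- `src/swallownet/preprocess.py` — volume discarding, motion QC, voxel means
- `src/swallownet/connectivity.py` — partial correlation, group mean
- `src/swallownet/construction.py` — degree-targeted and sweep thresholding
- `src/swallownet/metrics.py` — graph measures and hierarchy fit
- `src/swallownet/nulls.py` — rewiring nulls and small-worldness
- `src/swallownet/stats.py` — ROI/whole-brain sweep and rank-sum tests
- `src/swallownet/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model, conventions, parameter choices, limitations
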