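# dynet

Dynamic resting-state network analysis for parcellated fMRI, built around
the question of how cognitive fluctuations in Dementia with Lewy bodies
(DLB) show up as altered brain dynamics. The package implements, as a
tested and reusable pipeline, the full analysis chain used in that
literature — and ships a synthetic cohort generator so every stage can be
exercised and validated without access to any clinical data.

It is aimed at researchers in systems/network neuroscience who work with
region-by-time BOLD matrices (any parcellation; the motivating studies
use the 333-parcel Gordon atlas at TR = 3 s) and want time-resolved, not
time-averaged, network measures.

## What it computes

Given a parcel time series **X** (regions × time) and motion parameters:

1. **QC + filtering** — framewise displacement
   FD(t) = Σₖ |Δpₖ(t)| (rotations as arc length at 50 mm), DVARS as % of
   the grand-mean signal, frame flagging at FD > 0.25 mm / DVARS > 2.5%,
   nuisance regression, and a zero-phase Butterworth band-pass
   (0.071 < f < 0.125 Hz).
2. **MTD connectivity** — multiplication of temporal derivatives:
   coupling between regions *i, j* is the product of their SD-normalised
   first differences, smoothed over a 15-sample sliding window, giving a
   regions × regions × windows tensor.
3. **Temporal similarity** — the time-by-time Pearson matrix of brain
   patterns and two scalars: local similarity
   S_L = mean of r{tᵢ, tᵢ₊₁} over contiguous epochs (stationarity), and
   global similarity S_G = (Σ|r{tᵢ,tⱼ}| − n)/(n(n−1)) (size of the
   configuration repertoire). Patterns may be activity vectors per TR or
   vectorised connectivity windows.
4. **Time-resolved topology** — per-window Louvain modules; participation
   coefficient B_i = 1 − Σₛ(κ_is/k_i)² (between-module connectivity),
   module-degree z-score W (within-module connectivity), their joint
   "cartographic profile" histogram, and the k-means (k = 2) fraction of
   time each region spends in the low-participation, segregated state.
5. **Flexibility** — Hungarian matching of module labels across windows,
   then each region's switch fraction normalised by the module count.
6. **Behaviour** — Go/No-Go (SART-style) trial summaries and a
   closed-form moments fit of the simple drift-diffusion model (drift
   rate, boundary separation, non-decision time; diffusion coefficient
   fixed at 0.1).
7. **Statistics & gene maps** — permutation tests with covariate
   residualisation (Freedman–Lane style), Cohen's d, BH-FDR,
   Mann–Whitney U, permutation correlations, bin-wise cartographic
   correlation maps, and Spearman screens of regional difference maps
   against region × gene expression tables.

## Worked example

Run the bundled synthetic study — a control-like group (fast state
switching, higher between-module coupling) versus a DLB-like group (slow
switching, low coupling, state-dependent module membership), 20 subjects
per group, 60 regions, 200 timepoints:

```python
from dynet import run_synthetic_study

res = run_synthetic_study(n_per_group=20, n_regions=60, n_timepoints=200, seed=1)
for name, t in res.group_tests.items():
    print(f"{name:20s} p={t.p_value:.4f} d={t.cohens_d:+.2f}")
```

which prints (control minus DLB-like; negative d means DLB-like higher):

```
s_local              p=0.0442 d=-0.68
s_global             p=0.0380 d=-0.69
mean_participation   p=0.0106 d=+0.89
mean_flexibility     p=0.0914 d=+0.16
occupancy            p=0.0206 d=-0.78
```

The DLB-like group is more stationary (higher S_L: 0.9777 vs 0.9761),
has a smaller repertoire (higher S_G: 0.179 vs 0.148), is less
integrated (lower mean participation: 0.445 vs 0.501) and spends more
time segregated (occupancy 0.311 vs 0.235) — each significant by the
age/sex-adjusted permutation test. Flexibility shows no significant
group difference at this desk scale; `docs/methods.md` explains why the
match-then-count instability measure is dominated by estimation noise at
60 regions and 15-sample windows. A gene planted at Spearman ρ = 0.6
against the participation difference map is recovered by the
transcriptomic screen (realised ρ = 0.599, q ≈ 0) with background false
discoveries controlled.

The same study is available from the shell:

```bash
dynet run --out study_out --seed 1          # full pipeline + manifest.json
dynet simulate --out cohort_out --seed 1    # just the synthetic cohort files
dynet ddm-fit --in trials.csv --out fit.csv # drift-diffusion fit
```

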