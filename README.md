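# trsaxs — time-resolved high-throughput SAXS conformational screening

Fragment screens usually ask *whether* a compound binds. For allosteric
targets the sharper question is whether binding drives the functional
conformational change — for example a ligand-triggered monomer → dimer
assembly. `trsaxs` is an analysis pipeline for time-resolved,
plate-based small-angle X-ray scattering (SAXS) screens that answer that
question directly: each well's 300-ms scattering frames are reduced,
quality-controlled, compared against monomer/dimer benchmark states, and
ranked by transition kinetics, with orthogonal thermal-shift (DSF) and
microscale-thermophoresis (MST) triage folded in. It is written for
structural biologists and screening scientists who have 1-D reduced
profiles (`q, I, σ` text files) and a plate manifest.

## The quantities at the core

- **Guinier metrics** — ln I(q) = ln I(0) − q²R_g²/3 at low q gives the
  radius of gyration R_g and forward scattering I(0) ∝ c·MW per frame;
  dimerization doubles I(0) and raises R_g.
- **Volatility of ratio (V_R)** — similarity of two curve *shapes* over
  q = 0.015–0.15 Å⁻¹: the intensity ratio is averaged in 25 equal-width
  bins and summed as relative first differences,
  V_R = Σ|R_{i+1} − R_i| / ((R_{i+1}+R_i)/2). Zero for identical shapes,
  scale-invariant, exactly symmetric. Pairwise V_R values form a SAXS
  similarity matrix (SSM) whose rows are clustered into chemotypes
  (single-linkage AHC and k-means, cluster number by the Krzanowski–Lai
  index or the elbow rule).
- **Significance envelopes** — replicate benchmark V_R traces define a
  standard uncertainty σ̄ (per-time SDs averaged over the series); a
  sample is significant when its trace crosses mean ∓ 3σ̄.
- **k_VR kinetics** — each V_R-to-dimer time series is fit with
  V(t) = C + A·e^{−k_VR·t}; compounds are ranked and clustered by k_VR.
- **Z-factor** — Z = 1 − 3(σ_p+σ_n)/|μ_p−μ_n| over replicate
  monomer/dimer controls measures whether the two states are resolvable
  per well (0.5–1.0 = usable assay).
- **Triage** — Boltzmann T_m fits of DSF melts with QC, and MST
  amplitudes over a fixed excitation window, each called at 3 s.d.
  against DMSO references; hits are merged into verified /
  dual-verified status.

A seeded synthetic generator (`trsaxs.synth`) provides the full study
conditions — analytic sphere/tangent-dimer end states, first-order
conversion x(t) = x_inf(1 − e^{−kt}), frame noise, replicate controls
and a planted 4-chemotype, 12-compound library — so every stage is
validated end-to-end against known ground truth.

## Worked example

```
python analysis/01_simulate_plate.py      # raw plate -> scratch/plate/
python analysis/02_reduce_and_guinier.py  # subtraction + Guinier + Z-factors
python analysis/03_similarity_and_clusters.py
python analysis/04_kinetics_ranking.py
python analysis/05_triage_merge.py
```

`02` prints the control resolvability of the simulated plate:

```
Z(rg) = 0.993  (dimer 31.30 +/- 0.004 vs monomer 19.69 +/- 0.023)
Z(i0) = 0.999  (dimer 199.64 +/- 0.012 vs monomer 100.22 +/- 0.029)
```

i.e. the dimer control's R_g (≈31.3 Å) and doubled I(0) are separated
from the monomer's by far more than the replicate spread — the per-well
assay window is excellent. `03` reports the late-frame (2.1 s) SSM
clustering, where the Krzanowski–Lai index selects k = 4 and both
algorithms recover the planted chemotypes exactly, and `04` prints the
kinetic ranking:

```
Spearman(fitted k_VR, planted k) = 1.000 over 9 compounds
non-transitioning: ['F10', 'F11', 'F12']
```

— the fitted transition rates reproduce the planted rate order
perfectly, and the three inactive compounds are correctly flagged
non-transitioning. `05` merges the orthogonal assays:

```
DSF reference Tm = 65.43 C, sd = 0.161, 3-sigma cutoff = 0.48 C
MST reference amplitude = 955.7, sd = 0.81, cutoff = 2.44
hits: DSF 6, MST 6, dual-verified 5, QC-excluded 3
```

Library access is just as direct:

```python
from trsaxs import ScreenConfig, run_screen
report = run_screen(ScreenConfig(seed=42))
report.kinetics.head()          # label, k_vr, rank, cluster, ...
report.z_factors["rg"]["z"]     # 0.993
```

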