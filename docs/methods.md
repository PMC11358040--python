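# Methods

`trsaxs` implements a time-resolved high-throughput SAXS (TR-HT-SAXS)
conformational screen: from 1-D scattering frames and a plate manifest to
Guinier metrics, volatility-of-ratio (V_R) similarity, chemotype clusters,
single-exponential transition rates (k_VR), and orthogonal DSF/MST triage.
This note records the models, the defaults and why, the numerical choices,
and what the synthetic generator does and does not emulate.

## Reduction

Sample wells are paired with duplicate compound-matched buffer wells.  Per
frame t the buffer frames are averaged and subtracted:
I_sub(q, t) = I_sample(q, t) − s · mean_b I_buffer(q, t), sigmas combined in
quadrature.  The scale s defaults to 1.0 (matched buffers); it is an explicit
argument, and the default is recorded in run metadata, because some beamline
pipelines rescale backgrounds.  Frame times must agree to 1 ms.  Regridding,
when needed, is linear in (q, I) with no smoothing, so that noise statistics
entering V_R and the fits are not artificially damped; extrapolation is
refused.

## Guinier analysis

ln I(q) = ln I(0) − q²Rg²/3 is fit by weighted linear regression (weights
(I/σ)², i.e. σ_lnI = σ/I) on a window that starts at the first
positive-intensity point and shrinks from the high-q side until
qmax·Rg ≤ 1.3 (the globular-particle convention; configurable).  The shrink
iteration only ever moves the upper bound down, giving a deterministic fixed
point.  Note the Guinier approximation itself is biased for compact shapes:
for a uniform sphere the fitted Rg exceeds √(3/5)·R by ≈1.8% at
qmax·Rg = 1.3 and by <1% at ≤0.9; tests that check the closed forms use the
conservative window.

Aggregation is flagged by splitting the accepted window in half and refitting:
low-half Rg > 1.05 × high-half Rg, or a lowest-quartile mean residual above
2× the residual SD (systematic positive low-q curvature).  Windows under 10
points return "indeterminate" rather than a guess.  Detection presumes the
window still mostly reflects the main species — a minority large species at
~10–50% of I(0) (e.g. a 1e-5 number fraction of a 5× larger particle) is the
regime this catches; when an aggregate dominates I(0) outright, the adaptive
window tracks the aggregate and the curve is wrong in a way Guinier QC alone
cannot see.

The normalized Kratky transform is y = (qRg)²·I/I(0) against x = qRg; a
compact globule peaks at (√3, 3/e).

Assay resolvability uses the Z-factor
Z = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| with sample (n−1) SDs over replicate
control values; 0.5–1.0 is the usable band.

## V_R similarity

Two curves are compared through their intensity ratio over
q ∈ [0.015, 0.15] Å⁻¹, split into 25 equal-width bins (both configurable).
With A_i, B_i the in-bin mean intensities and R_i = A_i/B_i,

    V_R = Σ_{i} |R_{i+1} − R_i| / ((R_{i+1} + R_i)/2).

The summand is evaluated as 2|A_{i+1}B_i − A_iB_{i+1}|/(A_{i+1}B_i + A_iB_{i+1}),
which is algebraically identical and makes the swap symmetry bit-exact
(swapping curves maps R → 1/R, under which relative differences are
invariant).  Binning intensities before ratioing (rather than averaging
pointwise ratios) is what preserves that exactness.  V_R is zero iff the
binned ratio is flat, and is invariant to uniform scaling of either curve, so
no scale factor is fitted before comparison.  The bin count and equal-width
convention are this package's documented defaults; absolute V_R magnitudes
are therefore comparable only within one configuration.

Benchmark envelopes: replicate benchmark traces (monomer controls vs the
dimer reference; dimer controls' pairwise self-V_R) give a per-time mean and
sample SD; the SDs are averaged across the series into a single standard
uncertainty σ̄, and the significance threshold runs at mean − 3σ̄ for the
monomer benchmark (departure toward similarity) and mean + 3σ̄ for the dimer
self-similarity benchmark (entry into similarity).  The sense is an explicit
attribute per benchmark, not inferred.  Classification labels each time point
monomer-like / significant / dimer-entered and reports first crossing times.

## Clustering

"Chemotype" clustering operates on similarity-matrix rows (each sample's V_R
profile against all samples and controls) with Euclidean distance — the
`features: ssm_rows` convention; 1-D k_VR values are clustered directly.
Single-linkage agglomerative clustering (scipy) and k-means
(scikit-learn, k-means++ with 50 restarts, seeded) are both run, as
independent algorithms should agree on real structure.  Cluster number is
chosen by the Krzanowski–Lai index

    DIFF_k = (k−1)^{2/p} W_{k−1} − k^{2/p} W_k,  KL(k) = |DIFF_k / DIFF_{k+1}|

maximized over 2 ≤ k ≤ kmax−1 (ties to the smallest k, kmax = 8 by default
at the ~17-row scale), or by the elbow rule (largest second difference of
W_k).  Undefined KL entries (DIFF_{k+1} = 0) are excluded with a warning;
structureless scans are flagged low-confidence.  Both the KL-selected and a
forced-k (default 4) assignment are always reported at the early and late
clustering frames, since a single off-trend time point should not silently
change the cluster narrative.

## Kinetics

V_R-to-dimer traces are fit with V(t) = C + A·e^{−kt} (A, k ≥ 0; rising
observables like I(0) use C − A·e^{−kt}); nonlinear least squares with
initialization C₀ = last value, A₀ = first − last, k₀ from log-linearizing
V − C₀.  The plateau C is free — partial converters level off above the dimer
benchmark, and fixing C would bias their rates.  Fits are unweighted (no
per-point V_R uncertainty exists); a weights hook is provided.  A trace is
"transitioning" when A ≥ 2·SE(A) and k ≥ 10⁻³ s⁻¹.  Ranking is by
descending k, ties by amplitude then label; 1-D k values are clustered with
elbow-selected k-means.  Time-to-95% of the transition is 3/k.

Because V_R is a nonlinear (saturating) function of the converted fraction,
the fitted k_VR is a few percent above the underlying conversion rate for
full converters; the mapping is monotone, so rank order is preserved.
Kinetic fits use the full 10-s exposure framing (33 × 0.3 s frames) where
plateau and rate separate cleanly; the 0.3–3.0-s subset used for clustering
leaves a free plateau underdetermined at ≥5% trace noise.

## DSF / MST triage

Melt curves are fit with the Boltzmann sigmoid
F(T) = B + (P − B)/(1 + e^{(Tm−T)/a}) on the window truncated at the global
fluorescence maximum + 2 °C, excluding the SYPRO post-peak decay (the
truncation point is this package's convention).  QC fails curves that start
above 50% of their maximum (interference/pre-aggregation), reach their
maximum within the last 3 points (no transition), or fit with R² < 0.95.
Hit calls are k-sigma (default 3) against the DMSO reference mean using the
unrounded sample SD — printed, rounded SDs do not reproduce printed cutoffs.
DSF calls are two-sided (both stabilizers and NADH-like destabilizers
matter); MST amplitude calls are one-sided (amplitude-lowering).

MST traces are normalized to the pre-excitation baseline × 1000; the
amplitude is the mean over a 1-s window (4–5 s, inside the 3–23-s excitation
phase) averaged over three consecutive scans.  Titrations use
R(c) = R0 + ΔR·c/(K_d + c), reported ND when ΔR is insignificant or
K_d > 10× the top concentration.

## Synthetic generator

End states are analytic: a uniform sphere (radius R, form factor
P(u) = [3(sin u − u cos u)/u³]², Rg = √(3/5)R) and a tangent two-sphere dimer
(I = 2·scale·V²·P·[1 + sin(2qR)/(2qR)], Rg = √(8/5)R).  Per particle the
dimer scatters 4× forward; at equal mass concentration (number density
halved) I(0) doubles, so the number-weighted mixture obeys
I(0,t)/I(0,0) = 1 + x(t) exactly, with x(t) = x_inf(1 − e^{−k·t}).  The
default radius is 25 Å so the sphere's first form-factor zero
(u = qR ≈ 4.49) falls outside the 0.015–0.15 Å⁻¹ similarity window — real
protein profiles have no deep zero there, and a zero inside the window would
make ratio bins ill-defined under noise.  The dimer is the simplest analytic
shape with the required I(0) and Rg behaviour, not a structural model of any
protein.

Acquisition defaults: 0.3–3.0 s in 0.3-s frames (extensible to 10 s), q from
0.01 to 0.59 Å⁻¹ in 256 points, monomer I(0) = 100, flat buffer background
of 20 added to raw wells.  Noise is Gaussian on (post-subtraction-scale)
intensities with σ(q) = ε·√(I/I(0)) + ε/10 — counting-statistics-shaped
relative error with a floor.  Under this model the similarity window's
high-q bins (signal ≈2% of I(0)) carry ~7× the relative noise of the Guinier
region.  The default ε = 0.02 is set so that similarity clustering and rate
ranking on the default plate are faithful and seed-stable; control Z-factors
then sit at ≈0.99, the top of the usable band — with this noise shape a
single ε cannot simultaneously push Z down to ~0.6–0.9 and keep the V_R
stages clean, and the structural recoveries were judged the defining property
of the defaults.

The default 12-compound library plants four chemotypes — CX1 (k 1.4–2.0 s⁻¹,
full conversion), CX2 (k 0.4–0.8, x_inf 0.71–0.88), CX3 (k 0.9–1.2,
x_inf 0.19–0.24), CX4 (inactive) — whose converted fractions at the 2.1-s
clustering frame sit in separated bands (≈0.95–0.99 / 0.50–0.58 / 0.16–0.22 /
0), with thermal shifts (including one NADH-like −10.8 °C compound) and MST
amplitude drops shadowing conversion strength.  Controls: duplicate monomer,
triplicate dimer (static, fully converted), duplicate buffers.  Triage
assays plant a 23% pathological melt-curve fraction (count rounded; QC must
fail exactly those), per-curve Tm jitter of 0.15 °C around a 65.6 °C
reference (N = 216 reference wells, so the 3σ cutoff uses a well-estimated
spread), and MST scans at a 956.3-unit reference level with scan jitter
giving a reference SD near 1.4 units (N = 4).

What the generator does **not** emulate: interparticle structure factors and
concentration effects, radiation-damage evolution, capillary/bubble
artifacts, detector geometry (noise is independent per q point, whereas
azimuthal averaging correlates real errors), chemically realistic
dose–response, or partial-occupancy ligand kinetics.  Passing tests
therefore demonstrate that the analysis recovers the statistical structure it
assumes — two-state first-order conversion observed through noisy frames —
not that it is robust to every real-beamline pathology.

## Numerical and degenerate-input choices

- Sample (n−1) SDs wherever replicate spread is computed.
- Guinier window search only shrinks; < 5 usable points is an error.
- V_R requires strictly positive intensity in the window (RatioError
  otherwise) and ≥ 2 non-empty bins; bin index is floor((q − lo)/width) with
  the point at q = hi joining the last bin.
- Envelope construction requires ≥ 2 replicates on one time grid (1 ns
  tolerance on times).
- Exponential fits: non-convergence raises with diagnostics; constant traces
  fit but are non-transitioning.  k-means empty-cluster restarts are handled
  by scikit-learn's re-initialization.
- All stochastic steps take explicit seeds; identical config + seed gives
  byte-identical report JSON (keys sorted, floats via repr).
- Problem sizes throughout (12-compound plate, 10–33 frames, 256-point
  grids, 50-trace recovery ensembles) are chosen so a full screen runs in
  ~1 s and the whole validation suite in well under a minute on one core,
  while every statistical claim is still measured, not assumed.

## Known limitations

- Absolute V_R values depend on the bin convention; only orderings and
  cluster structure are comparable across implementations.
- The Guinier Rg bias for compact shapes (≈2% at qmax·Rg = 1.3) is inherent
  to the approximation, not fit error; Z-factors are unaffected (both
  control groups share the bias).
- Single-exponential k_VR is an effective rate; multi-step or stretched
  kinetics are out of scope by design.
- DSF Tm values from SYPRO-shaped curves carry a small common-mode offset
  from the post-peak decay; ΔTm against references fit the same way is
  unbiased.
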