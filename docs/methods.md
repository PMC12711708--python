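# Methods

This note documents the models, conventions and design choices behind
`lesionctx`, in the order data flows through the package.

## Coordinate and label conventions

Arrays are indexed `(x, y, z)` in world-aligned order; voxel centers sit at
`index * spacing` mm; all distances, areas and volumes are in mm, mm², mm³.
Label volumes hold one integer per voxel with rendering precedence
`tumor > vessel > adhesion > pleura > lung > body`, so labels are mutually
exclusive by construction. A companion caliber map stores the vessel caliber
(mm) at vessel voxels; it drives the "vessel ≥ 2 mm" gate everywhere.

## Phantom cohorts

A phantom is deliberately minimal anatomy: a spherical lung (default radius
20 mm in a 48³ 1 mm grid) inside soft tissue, a one-voxel pleural shell just
outside the lung boundary, an ellipsoidal tumor, straight or polyline tubular
vessels clipped to the lung, and optional adhesion patches (ball ∩ pleural
shell band, never reaching into the lung interior so that removing a patch
can reconstruct the anatomy beneath it). The tumor is placed along +x so that
its analytic surface sits the requested distance inside the lung boundary;
placement carries a +0.5-voxel (pleura) / +1-voxel (vessel) calibration
because voxel-center rasterization shrinks both surfaces by about half a
voxel each. Measured distances land within ±1 voxel of the request in ≥95% of
sampled phantoms (verified property). Infeasible requests (tumor breaching
the lung, lung not fitting the grid with a 2-voxel margin) raise an explicit
error; cohort sampling retries a bounded number of times (default 20) before
giving up.

Default cohort ranges: tumor radius 5–9 mm, tumor–pleura distance 0.5–11 mm
(the 0.5 mm floor keeps truly juxtapleural, contact-range tumors in the mix —
the cases where pleural complications concentrate and where adhesion edits
are applicable), vessel distance 2–8 mm with caliber 2–4 mm, adhesion patches
on 60% of cases with radius 1.5–5 mm. Covariates (age, sex, COPD, tumor-size
class, lobe, scanner stratum) are sampled independently of geometry, so under
the surrogate they are pure null stratifiers.

The surrogate risk model is logistic in z-scored concepts with planted signs:
distance→pneumothorax −2, proximity→hemorrhage +2, log-adhesion-area→pleural
reaction +2, intercepts −0.5, optional logit-scale noise (0 by default).
Outcomes are Bernoulli draws from the true risks; the train/test split is
stratified on the joint outcome pattern. One wrinkle is circular: risks need
z-scored concepts, z-scoring is train-fit, but the split is stratified on
outcomes. Generation therefore z-scores against full-cohort statistics; the
cohort then carries a `ZScorer` fit on the training split for all downstream
(audit) use, which is where the train-fit/test-apply contract matters.

What the phantoms do *not* emulate: airway trees, lobar fissures, lung
asymmetry, respiratory motion, intensity texture, annotation error. Passing
audits on phantoms therefore demonstrates correctness of the measurement and
audit machinery against planted ground truth — not robustness to real
anatomical variation.

## Concept extraction

* Minimum surface distance is the exact Euclidean distance between voxel
  centers via the sampled distance transform; it equals the brute-force
  all-pairs minimum (tested exactly).
* Pleural contact area counts tumor boundary voxels within 1.0 mm of the
  pleura times the voxel face area. The 1 mm threshold (one voxel) is a
  package choice, configurable.
* Vessel concepts gate on caliber ≥ 2 mm; proximity is 1/max(d, 0.5 mm) so it
  stays finite at contact; caliber ties at the minimum distance resolve to
  the largest caliber; with no qualifying vessel the distance is `inf`,
  proximity 0 and caliber NaN.
* Surface area uses boundary-face counting, chosen for oracle simplicity. The
  staircase bias is real: it overestimates a sphere's area by ~1.5×, so the
  sphericity π^{1/3}(6V)^{2/3}/A of a digital ball sits near 2/3 rather
  than 1; the cube value (0.806) is exact. Elongation is
  sqrt(λ₂/λ₁) of the voxel-coordinate covariance (1 for a single voxel).
* Adhesion extent is the voxel count (× face area) of adhesion components
  within 2.0 mm of the tumor, log-transformed as ln(1 + area) so zero-area
  cases are defined. The 2 mm contiguity threshold is a package choice.
* Z-scoring stores per-concept training means/SDs; constant columns are
  flagged and passed through untransformed.

## Counterfactual edits

All edits operate on label volumes only (no intensity inpainting) and certify
their achieved change; `valid` implies |achieved − target| ≤ 1.0 mm (one
voxel at the reference grid), labels stay exclusive, and the tumor stays
nonempty and connected.

* **Pleura edit (+5 mm default):** tumor voxels with pleural distance below
  (current minimum + δ) are relabeled lung — a level-set carve along pleural
  normals. Carving rather than translating keeps vessel relations untouched,
  so the counterfactual moves one concept at a time. Volume loss > 50% or an
  emptied tumor invalidates the edit (with reasons). Small tumors near a
  curved pleura can legitimately lose more than half their volume to a 5 mm
  carve; such cases are excluded, not silently clipped.
* **Vessel edit (−3 mm default):** the tumor grows inside a 2 mm-radius
  cylinder between its closest point and the nearest qualifying vessel point,
  claiming non-vessel voxels whose residual vessel distance stays ≥ target;
  the residual distance is floored at 0.5 mm (no overlap), and hitting the
  floor invalidates the edit.
* **Adhesion toggle:** add centers a 3 mm-radius patch at the pleural point
  nearest the tumor (3 mm read as patch radius; thickness = shell + 1 voxel
  outward); remove deletes the component nearest the tumor and reconstructs
  pleura/lung/body beneath it, so add-then-remove restores the volume
  bit-exactly. An added patch that cannot land contiguous with the tumor
  (> 2 mm away) is invalid — the concept it is meant to move cannot move.

## Causal-consistency audit

* Kendall's τ is tau-b (tie-adjusted; scipy backend, verified exactly against
  O(n²) pair counting) with seeded percentile bootstrap CIs (default B=1000).
* The isotonic violation rate sorts cases by concept, collapses concept ties
  to their mean risk, and reports the fraction of adjacent distinct-concept
  pairs whose risk change contradicts the prior; exact zeros are not
  violations. This definition is deterministic, enumerable by a brute-force
  oracle, and hits 0/1 at the monotone extremes; the alternative (residual
  mass off the isotonic fit) was considered and not used.
* Subgroup invariance fits OLS of logit(risk) (risk clamped to [1e-6,
  1−1e-6]) on the z-scored concept per stratum (strata under n=5 or with a
  constant concept are flagged and skipped), reports the max pairwise slope
  difference, and tests heterogeneity with a pooled group×concept interaction
  F-test, Holm-adjusted across every (pair, stratifier) audited in one call.
  When risks are an exact function of the concept (noise-free surrogate) the
  residuals are numerically zero and the F-ratio is meaningless; the
  implementation then falls back to the slope difference itself.
* Counterfactual sensitivity averages ΔRisk over valid edits; consistency is
  the percentage whose sign matches the expected response (prior direction ×
  induced concept change); exact-zero ΔRisk counts as inconsistent
  (conservative). Invalid/inapplicable edits are excluded and tallied with
  reasons. For the adhesion add, the audit draws candidate cases from the
  juxtapleural end of the cohort, since only there can the patch change the
  contiguous-area concept — this is the "applicable n" notion.
* ICC(2,1) is computed from two-way ANOVA mean squares (absolute agreement,
  single rater) with the Satterthwaite F-based CI; it matches
  `pingouin.intraclass_corr`'s ICC(A,1) to machine precision (cross-checked
  in tests, with pingouin as oracle only).

## Network components and toy training

All blocks are NumPy forward operators: the multi-scale attention gate with
channel allocation (50/25/25% across dilations 1/2/3; C=32 → 16/8/8), the
distance gate α·tanh(β·SDF)+γ, deformable convolution with trilinear sampling
and zero padding (exactly a standard convolution at zero offsets), a
five-level encoder with the {C0, 2C0, 4C0, 8C0, 16C0} schedule, and the three
task branches: ASPP (dilation rates 1, 6, 12, 18 — the canonical four-branch
set; note that only the small/intermediate rates are monotone in the pleural
gap, the largest rates pick up the far pleura) pooled over the tumor;
a deformable-convolution stack over the vessel channel pooled over dilated
tumor neighborhoods; and a Gabor bank (8 orientations × 3 scales, slice-wise
on the axial plane through the tumor centroid, as 2D texture operators)
with uniform-LBP histograms and attention-weighted (softmax-by-energy)
aggregation.

The composite loss is
`L = λ_seg (1 − Dice + α_mix L_focal) + λ_cls L_wBCE + λ_reg (1e-4 ||w||² + L_cons)`
with λ = (1.0, 0.5, 0.1), focal α=0.25, γ=2.0, class weights
(1.8, 2.3, 1.6) for (pneumothorax, hemorrhage, pleural reaction), and
probabilities clamped at 1e-7 before logs. The focal mixing weight α_mix is
exposed separately from the focal α (both default 0.25) because the two roles
are distinct. L_cons (multi-scale prediction consistency, mean-squared
disagreement after pooling to the coarsest grid) is computed and reported but
excluded from the toy gradient (a single-level segmentation head has nothing
to disagree with).

Toy training keeps the shared encoder stage *frozen* as seeded random-feature
extractors and fits only the FC heads (hand-written backprop, dropout 0.3 on
hidden layers) and a voxelwise logistic segmentation layer (analytic
Dice+focal gradient) with a NumPy AdamW (β₁=0.9, β₂=0.999, decoupled weight
decay 1e-4) under the cosine schedule
`LR(t) = LR_min + (LR_max − LR_min)(1 + cos(πt/T_max))/2`. Without a deep
learning framework, training convolutional encoders by backprop is not
practical on one CPU; frozen random features plus trained heads preserve the
frozen-predict contract the audits need and still learn the planted
geometry→risk relations. `TrainConfig` defaults record the full-scale
reference settings (lr 1e-3, batch 2, 4-step gradient accumulation, 200-epoch
T_max convention, C0=32, FC head [512, 256, 128, 1]); `TrainConfig.toy()`
raises lr_max to 5e-3 and updates per batch because the full-scale learning
rate cannot converge within a 30-epoch toy budget. Toy problem sizes
throughout: 32³ grids, C0=8, heads [32, 16, 8, 1], cohorts of 16–40 cases for
training and 30–500 for audits — chosen so the whole pipeline runs in minutes
on one CPU. Counterfactual evaluation of the toy model uses larger (48³)
phantoms with 7.5–9 mm tumors, where a +5 mm pleural carve is geometrically
feasible under the 50% volume-loss validity bound; branch features are in
physical units and transfer across grid sizes. Held-out AUC on ~12 test cases
is bounded by Bernoulli outcome noise (the oracle that predicts the true risk
scores 0.78–0.99 across seeds), so single-seed AUCs in the 0.7–1.0 range are
the expected behavior of a well-fit model, not a defect.

## Context graph and panels

Nodes are the tumor, pleural regions partitioned by distance band (contact
patch ≤1 mm, ring 1–10 mm — giving multiple pleural nodes), adhesion patches
and vessel segments (26-connected components), each carrying (size,
distance-to-tumor, caliber) features. Edges join nodes within 10 mm with
weight exp(−d/λ), λ=5 mm — both scales chosen at the order of the
counterfactual edit magnitudes (3–5 mm) and configurable; contact flags d ≤
1 mm; "crossing" means a vessel intersects the tumor's 5 mm expansion shell
(a package definition, flagged as such). Message passing is
h′ = h + Σ w·(M h) with M = identity, 1–2 rounds, purely summarizing: it
never mutates concepts, edits or predictions (hash-checked in tests). Panels
bind measured concept values, prior-direction arrows and (optionally)
cohort-level audit statistics into templated sentences; every number is
copied verbatim from its source structure, and regeneration is
deterministic.

## Preprocessing

Resampling to isotropic 1 mm uses trilinear interpolation for intensities and
nearest-neighbor for labels, preserving physical extent within a voxel. HU
normalization clips to [−1000, 400] and rescales affinely to [0, 1]. Lung
extraction thresholds strictly at HU < −500, removes border-touching air,
closes morphologically, and keeps interior components ≥10% of the largest
(both lungs survive; small airway/vessel fragments do not — the concrete
operator sequence is a package decision). Augmentation applies one shared
spatial transform (axial rotation ±15°, then elastic deformation with a
Gaussian-smoothed random field, α=100, σ=10, in voxel units — the field's
natural domain) to image and labels, then intensity-only Gaussian noise
(σ=0.05) and scaling (0.9–1.1), re-clipped to [0, 1]; axial rotation is the
default axis for thoracic volumes.

## Known limitations

* Phantom realism is deliberately minimal (see above); absolute audit values
  on phantoms do not transfer to clinical data — only the machinery does.
* The voxel-grid floor means "contact" and sub-voxel distances saturate at
  about one voxel; concepts below ~1 mm are quantized.
* Face-counting surface area (hence sphericity) carries the staircase bias.
* The toy network's encoder is not trained; conclusions about end-to-end
  representation learning at full scale cannot be drawn from it.
* The audits are post-hoc consistency checks against stated priors; they do
  not establish formal causality.
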