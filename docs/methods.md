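# Methods

## Spherical-cap reduction

All mechanical models in `dolinekit` reduce a curved, protein-coated
membrane domain to a spherical cap of fixed coat area `A_d`, described by
the single variable `u = 1 − cos ψ` (ψ the contact angle). The exact
relations

    A_p = A_d (2 − u)/2,   ΔA = A_d u/2,   R = √(A_d / 2πu),
    D = 2√(A_d(2 − u)/2π), Π = πD

conserve area identically (`A_p + ΔA = A_d`) and give every derived
observable in closed form, which lets the higher-level models be checked
against analytic oracles rather than against themselves.

The mechanical energy of one cap is a minimal Helfrich-type functional:
uniform bending of the coat against its spontaneous curvature,
`2 κ_c A_d (1/R − c0)²`; frame tension charged on the stored excess area,
`σ ΔA`; and an optional rim line energy `λ Π`. The flat limit `u → 0` is
handled analytically (`1/R → 0`), never by dividing by `u`. The sign
convention is that `c0 > 0` bends toward the cell interior, so a sphere
of radius `1/c0` carries zero bending energy — 50 nm for the full
caveolar coat, 200 nm for the Cav1-only coat.

With `λ = 0` the energy in `u` is `a u − b√u + const`
(`a = 4πκ_c + σA_d/2`, `b = 4κ_c c0 √(2πA_d)`), minimized at
`u* = min(b²/4a², 2)`. This closed form is the oracle used throughout the
tests; rimmed coats take a bounded 1-D numeric minimization instead.

## Parameters

| parameter | symbol | default | units | rationale |
|---|---|---|---|---|
| coat rigidity | κ_c | 20 | kBT | typical lipid/coat bending rigidity; tunable 10–40 |
| spontaneous curvature | c0 | 1/200 (cav1), 1/50 (ptrf) | nm⁻¹ | exact preset rationals; sets the relieved bud radius |
| rim line tension | λ | 0.02 | kBT/nm | order of lipid edge tensions; tunable 0–0.5 |
| protein footprint | a_p | 25 | nm² | ~5 nm protein diameter; tunable 10–50 |
| assembly penalty | δ | 0.01 (cav1), 0.875·e_f = 0.35 (ptrf) | kBT | calibrated, see below |
| barrier | ΔF_b | 10 | kBT | metastability allowance; tunable 0–50 |
| temperature | T | 298.15 | K | room temperature |
| coverages | φ̄ | 0.01, 0.03, 0.06 | – | representative dilute-to-dense protein fractions |
| tension grid | σ | 60 log-spaced in [10⁻⁴, 1] | kBT/nm² | spans sub-physiological to lytic tensions (≈ 4×10⁻⁴–4 mN/m) |
| domain-area bounds | A_d | [10³, 10⁶] | nm² | 35 nm – 1.1 µm projected scale |

Internal tension unit is kBT/nm²; `convert_tension` maps to mN/m (= pN/nm)
using k_B T = 4.116 pN·nm at 298.15 K.

## Single-domain two-state model

The continuum shape dynamics of a deforming domain are replaced by two
quasi-static branches: *assembled* (cap at its optimal `u*(σ)`) and
*dispersed* (all `N_p = A_d/a_p` proteins flat in the membrane, each
paying the frustration energy `e_f = 2 κ_c a_p c0²`). Their free-energy
difference is

    Δ(σ) = E(u*; σ) + N_p δ − N_p e_f ,

so assembly is driven purely by curvature relief (`e_f > δ`), consistent
with coats that disperse rather than aggregate when flattened. A finite
barrier `ΔF_b` lets each branch persist metastably: on loading the
assembled branch survives until `Δ(σ) ≥ +ΔF_b`; on unloading the
dispersed branch survives until `Δ(σ) ≤ −ΔF_b`. Grid transitions are
refined by bisection between neighbouring grid points (1e−6 relative in
σ). For a rimless interior optimum the equilibrium transition is closed
form, `σ* = 8πκ_c (e_f − δ)/(δ A_d)`, and is cross-checked against a
root-finder to 1e−8.

δ is calibrated per coat: `δ_ptrf = 0.875 e_f` keeps the caveolar domain
super-hemispherical (`u* ≈ 1.46 > 1`) when it reaches the up-transition,
producing a snap with hysteresis (σ_up/σ_down ≈ 1.44 at ΔF_b = 10 kBT),
while `δ_cav1 = 0.01 kBT` lets the doline unfold to `u* < 0.1` before
dispersing, so no jump exceeds 0.3. Default areas are one full bud of
coat for ptrf (`A_d = 4π/c0² ≈ 3.14×10⁴ nm²`) and a doline-scale patch
for cav1 (`2×10⁵ nm²`, several-hundred-nm projected diameter). Kinetics
(rates of snapping, thermal activation over the barrier) are out of
scope: the model is strictly quasi-static.

## Ensemble model

The ensemble treats a monodisperse population: `n` identical domains per
unit projected membrane area, each with the same `(A_d, u)`, in exchange
with a dispersed protein pool at fixed total coverage `φ̄` (protein
conservation `n A_d + φ_disp = φ̄` holds exactly; the coat is taken
close-packed, protein fraction 1 inside domains). The free-energy density

    f = n [E(A_d, u; σ) + (A_d/a_p) δ] + (φ_disp/a_p) e_f + n (ln(n a_p) − 1)

adds the domains' translational entropy with reference area `a_p` (the
reference only shifts `f` by a constant times `n`). Minimization is over
the box `(q, ln A_d, u)` with condensed fraction `q = nA_d/φ̄ ∈ [0, 1]`,
which encodes the conservation constraint exactly; a deterministic
5×5×5 multi-start lattice feeds L-BFGS-B, ties within 1e−10 break toward
smaller `u` then smaller `A_d`, and tension sweeps warm-start each point
from the previous minimizer (direction-dependent continuation). The
optimizer is verified against exhaustive 20×20×20 grid searches on random
parameter draws. `regime_report` then summarizes each sweep: Spearman
trends of `n` and `A_d` against σ, contact angle at the lowest tension,
upper-half-sweep shape variation, and strain released over the lowest and
highest tension deciles with its coverage dependence.

### Known limitation: entropy-driven fragmentation

Within this reduced functional the domains' translational entropy
(~8–15 kBT per domain at the densities of interest) outweighs the rim
penalty at small areas (λΠ ≈ 2 kBT at `A_d = 10³ nm²` with the default
λ), while closed buds (`u = 2`, zero rim) undercut any large shallow cap
at very low tension. The equilibrium consequently sits at the small-area
bound for both coats across the default tension range: many small,
shallow caps whose depth decreases with tension. The low-tension contact
angle of the Cav1 coat is therefore far below 90°, as expected for
dolines, but two phenomena of the full continuum picture are *not*
reproduced by this reduction: the splitting trend of large Cav1 domains
(domain area is already pinned at the bound, so no decreasing-area trend
develops) and the shape-invariant number reduction of caveolae (no
R = 50 nm bud branch is the global minimum here). Both would require
neck/transport energetics absent from a monodisperse spherical-cap
ensemble with uniform coat enrichment. The corresponding end-to-end
checks in `tests/test_acceptance.py` document this honestly: they encode
the expected phenomenology and fail against the reduced model. The
single-domain model, which encodes bistability explicitly, does exhibit
the snap/continuous dichotomy.

## dSTORM pipeline

Order is fixed and logged: read → filter → merge → homogenize → cluster
→ measure → stratify; there are no stochastic steps, so reruns are
bit-identical.

* **Filter**: strict inequalities, intensity ∈ (300, 5000) photons,
  uncertainty < 35 nm, PSF sigma < 300 nm.
* **Merge**: re-blinking fluorophores produce runs of events in
  consecutive frames; chains are grown greedily in frame order (an event
  joins the nearest open chain whose last event was in the previous frame
  and within 20 nm, ties to the oldest chain) and collapse to one record
  at the unweighted mean position with frame = first, intensity summed,
  uncertainty = min, sigma = mean. Chain seeding and attribute
  aggregation are conventions of this package.
* **Homogenize**: keep the first `k` frames, `k` minimizing
  |density(k) − 2×10⁻⁴ blinks/nm²| over the segmented ROI area
  (computed on the post-merge table; ties toward smaller `k`; deviations
  compared on the count scale so exact ties stay exact). Samples that
  never reach the target keep all frames with a warning, so sparse cells
  are not discarded.
* **Cluster**: DBSCAN with ε = 20 nm, minpts = 30, core points counting
  themselves. The implementation is deterministic and order-independent:
  clusters are numbered by smallest core index and border points join the
  lowest-id eligible cluster. It is tested for partition-identity against
  a union-find oracle and scikit-learn's DBSCAN.
* **Measure**: cluster area is the convex hull of member coordinates
  (the simplest unambiguous "boundary blinks" area; an alpha-shape is a
  possible extension), blink density = members/area, Feret diameter = max
  pairwise distance over hull vertices. Hulls below 1 nm² are flagged
  degenerate and excluded from density statistics. With an ROI polygon,
  clusters whose hull is not strictly inside it are excluded; with only
  an area given, exclusion is skipped and logged.
* **Stratify**: small (< 25²π nm²), medium ([25²π, 50²π)), large
  (≥ 50²π); per-stratum median blink density (mean of the central pair
  for even counts; empty stratum → missing, not zero) and cluster count
  per µm² of ROI.

Coordinates are continuous nm in a Cartesian frame; frames start at 1.

## Synthetic data

The blink generator emulates the statistical structure of a dSTORM
table: K Gaussian clusters (default 10 × 100 blinks, sd 8 nm) with
centres kept ≥ 150 nm apart and ≥ 200 nm from the ROI border, uniform
background blinks (5% of cluster blinks), frames uniform over 9000, and
attribute marginals inside the filter window (lognormal intensity,
median 1000 photons; gamma uncertainty, mean 15 nm; normal PSF width
150 ± 20 nm) plus 2% deliberately out-of-window records to exercise the
filter. On a 2×2 µm ROI the homogenization target corresponds to 800
retained blinks, leaving ≈ 75 per cluster — comfortably above minpts.
What it does **not** emulate: photophysics (blinking kinetics,
duty-cycle correlations), drift, camera noise, or non-Gaussian cluster
shapes; recovery tests on it therefore demonstrate pipeline correctness,
not robustness to those real-data effects.

The force-curve generator solves the implicit cantilever balance
`k(d − d_0) = Hertz(E, (z − z_c) − (d − d_0))` per displacement sample,
so noiseless curves satisfy the model to machine precision; Gaussian
noise is added to the deflection only. The GP generator inverts the GP
formula at fixed I490. All generators are pure functions of
(params, seed); one generated table per generator is pinned in the tests
as a regression golden.

## Hertz fitting

`fit_hertz` estimates (E, z_c, d_0) jointly by Levenberg–Marquardt on
force residuals `k(d − d_0) − Hertz(E, δ)` with `δ = (z − z_c) − (d − d_0)`
clipped to the contact branch (δ ≥ 0), Poisson ratio fixed at 0.5. The
deflection offset initializes from the pre-contact baseline (first fifth
of samples) and the contact point from where the baseline-subtracted
force first exceeds its noise floor; the fit is deterministic given the
data. Joint estimation was chosen over pre-detecting the contact point
because the latter biases E when the contact is soft. Verified: noiseless
round-trip < 0.1%, median error < 2% on a 20-curve ensemble at 2 nm
deflection noise.

## Numerical conventions

Energies in kBT (kBT ≡ 1 internally), lengths nm, tensions kBT/nm² in
the models; SI (m, N, Pa) in the AFM utilities. Flat and closed-bud
limits are analytic. The ensemble reports non-convergence via a
`converged` flag and falls back from a failed warm start to the full
multi-start lattice rather than aborting a sweep. All randomness flows
through explicit integer seeds; there is no hidden global state.
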