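# Methods

`cardinv` implements the two standard equivalent-surface-source models of
noninvasive inverse electrocardiography on boundary-element volume
conductors, together with their sensitivity-map comparison and two ways
of combining them.  This note records the models, the numerical choices,
and what the synthetic study conditions do and do not establish.

## Source models

The current sources of the heartbeat are transmembrane currents inside
the myocardial wall.  Potentials recorded outside the heart cannot
resolve intramural structure: any source distribution is externally
equivalent to a source layer on a surface enclosing it.  Two such
equivalent layers are in practical use.

**Epicardial potentials (EP).**  A closed surface just outside the heart
is treated as an internal boundary of the volume conductor, carrying
impressed potentials φ; everything inside it is ignored.  The linear map
to the electrodes, `V(t) = T φ(t)`, is inverted per sample by Tikhonov
regularization,

    min_φ ‖V_t − Tφ‖² + λ²‖Rφ‖² ,

with R = I (order 0, small solutions) or the mesh Laplacian (order 2,
smooth solutions).  λ is chosen once per beat from the pooled QRST
samples by the L-curve maximum-curvature rule or the CRESO criterion
(first interior local maximum of the difference quotient of λ²‖φ_λ‖²);
fixed values and per-sample selection are configuration switches.
Activation and repolarization times are read off the reconstructed
electrograms as the steepest downslope in the QRS window and the
steepest upslope in the T window (central differences, earliest sample
on ties; flat channels are flagged missing).

**Equivalent dipole layer (EDL).**  A current dipole layer covers the
entire myocardial surface — epicardium plus endocardium, both oriented
out of the wall — with strength proportional to the local transmembrane
potential (TMP).  The TMP follows a single template parameterized by the
node's activation time τ and repolarization time ρ:

    D(t; τ, ρ) = resting + amplitude · F((t−τ)/w_d) · F((ρ−t)/w_r),

F the logistic function.  The published construction derives its
template from recorded human T waves, which are not available here; the
product-of-logistics surrogate keeps the physiologically essential
features (monotone upstroke of width `w_d`, plateau, monotone recovery
of width `w_r`, correct asymptotes) and is smooth in (τ, ρ), so the
Jacobian of the forward ECG is analytic.  Defaults: resting −85 mV,
amplitude 100 mV, w_d = 1.5 ms, w_r = 30 ms — conventional ventricular
values, not fitted to any recording.

The EDL inverse estimates (τ, ρ) for all nodes simultaneously:

    min_{τ,ρ} Σ_t ‖V(t) − A d(τ,ρ,t)‖² + λτ²‖Lτ‖² + λρ²‖Lρ‖² ,

with L the cotangent mesh Laplacian.  The problem is non-convex and is
solved by Levenberg–Marquardt from a fastest-route initial estimate:
every myocardial node is tried as an ectopic focus at each velocity of a
small grid, activation spreads as graph-geodesic travel time,
repolarization follows either a uniform action-potential duration (APD)
or the electrotonic rule ρ = τ + APD₀ − s·(τ − mean τ), and candidates
are ranked by the relative RMS misfit of their forward ECGs with a free
global onset shift fitted per candidate (a correlation metric is
available behind a flag).  Multi-start (default 3) optimizes the
top-ranked candidates and returns the best data fit, keeping the others
as explicit alternatives.  The constraint ρ > τ is enforced by
optimizing (τ, log(ρ−τ)).

Because the data residual separates as `A[i,j]·g[j,t]`, the
Gauss–Newton normal matrix is assembled from Hadamard products of `AᵀA`
with small node-by-node Gram matrices; the full Jacobian is never
formed, which makes an LM iteration on the default problem (648
parameters, 400×90 residuals) essentially free next to the transfer
assembly.

λτ, λρ default to 0.01 and 0.005, fixed empirically on the default
study conditions (the first of the two published calibration options);
the second option — bisect λ until ‖Lτ̂‖ matches a prescribed
smoothness level — is `auto_lambda`.

## Volume conductor and transfer matrices

Interfaces are closed triangle meshes; the solver is double-layer
collocation with analytic van Oosterom–Strackee solid angles, vertex
(hat-function) lumping, and diagonal closure by the Gauss identity, so
constant potentials are reproduced exactly.  The insulated body leaves
the potential defined up to a constant; the system is deflated by a
rank-one area-weighted term and potentials are re-referenced to zero
mean over the electrodes.  The default conductor is a homogeneous torso
(0.2 S/m); nested piecewise-homogeneous compartments are supported by
the same assembly.  Against the closed-form Legendre-series solution for
an eccentric dipole in an insulated sphere the solver is accurate to
0.3% relative RMS at refinement 3 and 0.06% at refinement 4 (the series
oracle lives in `cardinv.reference` and is not part of any production
path).

`T` (EP flavor) is built from the boundary integral equations of the
passive annulus between the source surface (Dirichlet data) and the
torso, eliminating the unknown normal current through the single-layer
operator (edge-midpoint quadrature; analytic vertex-singular formula for
incident triangles).  Row sums equal 1 by construction — a uniform
impressed potential yields the same uniform body potential.

`A` (EDL flavor) maps unit dipole-layer strength per vertex patch to the
electrodes through the same conductor solve; its rows sum to zero
because a closed uniform layer is externally silent.  The dimensionless
layer scale (conductivity ratios folded together) defaults to 0.28,
chosen so a full-amplitude depolarization front produces ~1 mV peak
body-surface QRS on the default geometry — a unit convention, not
physiology.

Sensitivity maps divide a transfer row by patch areas (per cm²) at a
stated activity scale (15 mV for EP, template amplitude for EDL).  With
two *closed* sheets the epicardial Dirichlet boundary separates the
endocardium from the passive region exactly, so EP endocardial columns
are identically zero; published maps show small nonzero values because
real epi/endo sheets connect at the base.  The EDL endo/epi sensitivity
ratio on the default fixture is ≈0.8.

## Synthetic study conditions

`sources.generate_dataset` builds the default fixture: a spherical torso
(R 200 mm, refinement 3, 642 vertices), an eccentric heart at
(−40, 0, 0) with epicardial (R 50) and endocardial (R 35) spheres at
refinement 2 (162 nodes each), 400 electrodes by deterministic
farthest-point sampling of the torso vertices.  Dense sampling matters:
at 200 electrodes the EP transfer's smallest singular value drops by an
order of magnitude and near-null source components become unrecoverable.
The two myocardial sheets are deliberately left unconnected at the base
(a simplification of real geometry); nearest-neighbour transmural
conduction links let fastest-route activation cross the wall, with the
wall thickness (15 mm) as the link length scale.

Activation is focal pacing (default: the epicardial node nearest the
chest wall, onset 10 ms) spread at 1.0 mm/ms; repolarization uses the
electrotonic rule with APD₀ = 220 ms and slope 0.25; ECGs are sampled at
1 kHz over a 0–450 ms QRST window; sensor noise is 20 µV additive white
Gaussian per channel (no baseline wander, no line interference).  The
EDL fitting grid subsamples to 5 ms.  EP experiments use truth
epicardial electrograms shaped as the mirrored template (−0.15·d,
~15 mV deflections), the scale of real epicardial electrograms.

What passing these conditions shows: the estimators are correct and
stable implementations of their defining optimization problems, with
recovery limited by noise and regularization rather than by coding
errors — the inverse crime (same forward model for data and inversion)
is used deliberately and labelled.  What it does not show: accuracy on
real torsos (geometry error, anisotropy, regional TMP variation,
breathing/motion, electrode misplacement are all absent), so the
recovery numbers here are upper bounds, not clinical claims.

## Numerical choices

- **CRESO grid**: λ grid spans [1e-3, 10], four decades around the
  largest singular value of T (≈1 on the default fixture).  Extending
  the grid far below the singular spectrum's top creates spurious local
  maxima of the CRESO function (one per noise-amplified cluster of small
  singular values), a known failure mode of the first-local-max rule.
- **L-curve**: curvature of the log-log curve via cubic-spline
  derivatives on a dense parameter grid; ties break toward smaller λ.
- **LM controls**: initial damping 1e-3, factor 10, max 50 iterations,
  stop on relative objective decrease < 1e-8 or step < 1e-3 ms; accepted
  steps never increase the objective.
- **Timing metrics**: one global least-squares time shift (pooled over
  AT and RT differences) is removed before MAE/RMSE and reported,
  because simulation time zero is arbitrary relative to reconstructed
  onset.  Localization error is Euclidean by default (geodesic behind a
  flag); ties at the activation minimum resolve to the closest
  candidate.
- **Degenerate inputs**: zero-area triangles, non-manifold edges,
  inverted orientation, disconnected routing graphs, flat electrogram
  channels and ρ ≤ τ all raise structured errors or missing-value flags
  rather than propagating silently.

## Combined inverses

*Sequential*: EP reconstruction → AT/RT extraction gives the epicardial
start (missing nodes filled by neighbour means); endocardial timing is
initialized by a focal scan over endocardial nodes with the epicardial
values held fixed (candidate travel times propagate both from the focus
and from the fixed epicardial front); LM then refines all nodes.  Its
advantage over EP alone is exactly that endocardial timing is produced.

*Merged*: the two objectives are summed and coupled by an explicit
epicardial-consistency penalty

    μ Σ_{j∈epi} Σ_t (φ_j(t) − γ_j s_j(τ_j, ρ_j, t))²,

where s_j is the template-shaped local electrogram surrogate and γ_j a
per-node gain refit each outer iteration.  As printed, the two component
objectives share no variable; some explicit coupling is required to make
the minimization "simultaneous", and this penalty is the single largest
design addition in the package — the literal decoupled form is recovered
exactly at μ = 0.  The solver is block coordinate descent (linear
φ-block and gain refit; LM timing-block with coupling rows appended), so
the joint objective is non-increasing by construction; the run report
always prints all six components, keeping both component fits visible.
Whether the merged inverse is *more accurate* than its parts is left
open by design; the package provides the machinery and the bookkeeping
to test it.

## Known limitations

- Homogeneous torso by default; lungs/blood need conductivities from the
  user.  Anisotropy is out of scope entirely.
- One template for all nodes; no regional TMP variation, no ischemic
  resting-potential shifts, single beat only (the template covers one
  cycle).
- Spherical fixture geometry; no image-derived anatomy, atria, or
  deforming meshes.
- The basal epi/endo connection is not meshed; transmural links are a
  conduction shortcut, not geometry.
- Graph-geodesic activation ignores wavefront curvature and fiber
  direction; initial estimates only need to rank candidate foci.
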