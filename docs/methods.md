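# Methods

`neckforce` estimates individual cervical muscle forces from three head
markers and three anthropometric parameters, and screens for functional
deficits by comparing a subject's head-motion envelope with an idealized
simulated envelope.  This note records the models, the numerical choices,
and the places where the design was genuinely open.

## Rigid-body head–neck model

The cervical column is reduced to a serial chain with two lumped
articulations — lower (T1 to mid-cervical) and upper (mid-cervical to
skull) — each carrying three rotational degrees of freedom ordered
flexion–extension (about +y), lateral bending (about +x, positive to the
left), and axial rotation (about +z, positive to the left).  Frames are
torso-fixed: x anterior, y left, z superior; gravity is 9.81 m/s² along
−z.  Two bodies carry mass: the lower cervical segment (1.2 kg cylinder)
and the head (a sphere of radius 9 cm whose mass is the personalized
head mass; the body includes the upper cervical column).  The equations
of motion

    M(q) q̈ + C(q, q̇) q̇ + G(q) = R(q) f + τ_passive + Jᵀ F_ext

are evaluated by a recursive Newton–Euler pass (gravity, Coriolis and
inertial terms exactly); the mass matrix, when needed, comes from the
unit-acceleration identity.  Passive joint moments are linear:
stiffness 0.5 N·m/rad and damping 0.01 N·m·s/rad per DOF by default —
small relative to gravitational demands, and zeroable for analytic
tests.  An energy-conservation test on a passive free swing validates
the M/C/G assembly.

Three personalization parameters scale the model: neck length scales the
chain and every longitudinal coordinate; shoulder width scales the
lateral coordinates of shoulder-anchored muscle origins (trapezius,
clavicular muscles, levator scapulae, omohyoid); head mass sets the head
body's mass and scales its inertia.  Population statistics for the three
parameters (mean and full covariance, derived from a large military
anthropometric survey) ship with the package; profiles are drawn from
the multivariate normal with rejection of nonpositive or >5σ draws
(negligible probability, guarantees plausibility).  The printed
covariance between head mass and neck length (−0.001) is nearly zero and
is used verbatim.  Units are kg/cm at the interface and SI internally.

### Muscle geometry

All 72 muscles (36 bilateral pairs, named after the standard cervical
model inventory) are straight lines from origin to insertion, with no
via points or wrapping.  The packaged attachment table places each
muscle in an anatomically sensible compartment (anterior hyoid chain,
sternocleidomastoid group, scalenes, deep prevertebral flexors,
posterior superficial and deep extensors, suboccipitals) with plausible
maximal isometric forces; it does not claim digitized-cadaver accuracy.
The coordinates were iterated until a linear-programming feasibility
check showed the default model can balance every frame of the
standardized motion suite within the muscle force bounds — a property of
the model itself, verified independently of any learning stage.
Moment arms are computed analytically from point Jacobians and satisfy
the tendon-excursion relation (moment arm = −∂l/∂q) to finite-difference
precision.  A documented deep/superficial classification drives the
optimization weights below; it extrapolates anatomically from the
exemplars (longus colli and multifidus-type stabilizers deep;
sternocleidomastoid and trapezius superficial) and is user-overridable.

An 8-pair reduced set (16 muscles spanning deep/superficial classes and
flexor/extensor/lateral/rotator actions) is the default for desk-scale
runs; the full 72-muscle set is a flag away.

## Enhanced static optimization

Net joint moments from inverse dynamics are distributed over muscles by
solving, per frame,

    min_f  Σ w_i (f_i/f_i^max)²  +  λ₁ Σ Φ_i  +  λ₂ Σ ḟ_i²
    s.t.   R f = τ,   0 ≤ f_i ≤ f_i^max,   (optional) f_j ≈ κ f_k

with w_deep = 0.8, w_sup = 1.2 (biasing recruitment toward deep
stabilizers), λ₁ = 0.01, λ₂ = 0.001, κ = 1.0.

Open choices, resolved as follows:

* **Temporal scope.** The objective is solved frame-sequentially, with
  ḟ discretized backwards against the previous frame's optimum
  (receding-horizon reading); each frame is then a strictly convex QP
  with a unique solution.  The first frame has no history and runs with
  the rate term off.
* **Metabolic term Φ.** No standard functional form exists for a
  per-frame metabolic proxy; the default is the linear normalized-force
  form Φ_i = f_i/f_i^max, which keeps the frame problem convex.  A
  selector isolates this choice.
* **Rate-term scaling.** ḟ is taken as the *per-frame normalized force
  increment* (f_i − f_prev,i)/f_i^max, so λ₂ weighs smoothness against
  activation on a common dimensionless scale.  Penalizing a raw N/s rate
  at 100 Hz would dominate the objective by orders of magnitude and turn
  the forces into a heavily hysteretic low-pass of the demand — at which
  point muscle force is no longer a function of pose and anthropometry,
  contradicting the premise of the surrogate stage.  (Empirically, a
  nearest-neighbour oracle caps at R² ≈ 0.7 under the raw-rate reading
  and reaches ≈ 0.999 under the normalized one.)
* **Bilateral symmetry.** `hard` mode imposes f_j = κ f_k exactly as
  equality rows; `soft` (default) adds a small quadratic penalty
  μ(f_j − κ f_k)², applied only when the commanded motion is sagittally
  symmetric, since asymmetric tasks legitimately demand asymmetric
  forces; `off` disables it.  The κ ± 0.05 band is retained as a
  post-hoc violation diagnostic.

The QP is solved by folding the equality constraint into a quadratic
penalty (weight 1e8), solving the resulting bound-constrained least
squares with BVLS (finite, deterministic), and then re-solving the exact
equality-constrained KKT system on the identified free set.  Moment
residuals land near 1e-11 N·m against a 1e-6 N·m tolerance; frames whose
demand lies outside the feasible wrench set are flagged infeasible, never
silently accepted.  The solver path is deterministic: identical inputs
give bit-identical forces.  Cross-checks: a closed-form two-synergist
KKT solution, a dense grid search, and an independently coded classical
static optimization (SLSQP + exact reduced-KKT polish) at 1e-6 N.

## Motion synthesis

Standardized tasks are raised-cosine cycles (neutral → +A → neutral →
−A → neutral, zero velocity at turning points) in flexion–extension,
lateral bending, and axial rotation, plus a combined task (simultaneous
half-amplitude flexion and rotation, 90° out of phase) and a seeded
"spontaneous" mode (band-limited random sinusoids, 0.1–0.5 Hz, tapered).
Default total amplitudes: 0.8 rad flexion–extension, 0.6 rad lateral
bending, 1.0 rad axial rotation, split evenly between the two
articulations; 100 Hz sampling.  Restricted variants attenuate
excursions into named direction sectors (signed half-ranges such as
`flexion` or `right_rot`) by a factor in (0, 1], leaving all other
directions untouched.

Repeated recordings are fused by classical DTW (Euclidean local cost,
symmetric steps, no window): all series are warped onto the medoid
(minimum total pairwise DTW distance) and averaged point-wise.  The
medoid reference and the symmetric-step variant are package choices;
other DTW variants would serve equally.

## Surrogate networks

Each muscle gets an independent feedforward net 12 → 64 → 32 → 1 (ReLU
hidden layers, linear output).  The 12 features are the nine torso-frame
marker coordinates (TP, LH, RH) and the three anthropometric parameters;
all 12 are Z-score standardized (population-SD convention, zero-variance
guard), as are the per-muscle labels during training, with statistics
fitted on the training split only.  Rows are split 20% test, then 20% of
the remainder validation (64/16/20 overall), shuffled with the run seed;
a group-by-model split mode exists for generalization studies.  Negative
raw predictions are clipped to zero after de-standardization.

Training is full-batch L-BFGS, at most 800 iterations, with the
validation loss checked every 100 iterations and early stopping at
patience 200; each muscle's net is seeded `seed + muscle_index`.
L-BFGS was chosen over first-order mini-batching because several force
targets are mostly zero with short, sharp recruitment bursts; on such
skewed targets adaptive-moment descent reliably stalls in poor optima
(test R² ≈ 0.80) although the mapping itself is learnable to ≈ 0.999
(nearest-neighbour oracle), while L-BFGS reaches R² ≥ 0.99 per muscle.
An adaptive-moment mode (lr 1e-3, batch 256) remains available.

## Activation inversion and sEMG

Predicted forces map to activations by the Hill-type relation
a = F / (F_max · f_l(l̃) · f_v(ṽ)), clipped to [0, 1] with the clip rate
reported.  The multipliers' functional forms are package defaults (the
source states none): Gaussian force–length exp(−((l̃−1)/0.45)²) and a
Hill hyperbola force–velocity with curvature 0.25 and eccentric plateau
1.4.  For the straight-line muscles, l̃ and ṽ are path length and path
velocity normalized by the neutral-pose rest length (and a maximal
shortening velocity of 10 lengths/s).

sEMG channels (1000 Hz) become linear envelopes via a 4th-order
Butterworth 20–450 Hz band-pass, full-wave rectification, 10 Hz
low-pass, MVC normalization (after envelope extraction, in that order),
and resampling to the 100 Hz marker timebase.  Filtering is zero-phase
(forward–backward), which doubles the effective order but avoids phase
lag when correlating envelopes with predictions.

## Envelopes, IoU, and deficit screening

A marker's reachable region is the alpha shape of its trajectory points;
the default alpha = ∞ (convex hull) suits the near-convex clouds of
smooth head motion, with finite alpha available (Delaunay tetrahedra
filtered by circumradius).  Volumetric IoU is evaluated on a shared
axis-aligned voxel grid over the joint bounding box (64³ default;
deterministic, unlike Monte-Carlo).  A subject is matched to the
database model maximizing the sum of the three per-marker IoUs (equal
importance; ties break to the lowest model id).  Muscle-level screening
uses the ratio of peak predicted force, actual / ideal trajectory, with
thresholds 0.85 (possible impairment) and 1.15 (possible compensation) —
package defaults for the qualitative "reduced / elevated" reading —
and a floor guard (ideal peaks below 1e-6 N are reported undefined).
Per-marker IoUs between two subjects are compared with a paired t-test
(df = n−1, two-sided).

## Scaled-down study conditions

Desk-scale defaults, used by the test suite and the acceptance script:
20 sampled anthropometric profiles, the 16-muscle reduced set, and a
four-task standardized suite (5 s flexion–extension, 5 s lateral
bending, 5 s axial rotation, 6 s combined; 2 cycles each at 100 Hz),
giving ≈ 2,100 frames per profile and ≈ 42,000 dataset rows.  The
restricted-motion "patient" fixture attenuates the flexion and
right-rotation sectors to 60%.

## What the synthetic data does and does not emulate

The generator reproduces the structure of the study — anthropometric
diversity from printed population statistics, standardized cyclic tasks,
marker kinematics consistent with a rigid head, forces from a single
deterministic redundancy principle — but not measurement noise, marker
occlusion or soft-tissue artifact, motor variability between repetitions
of a task, co-contraction beyond what the weighted objective induces, or
the anatomical detail of a full vertebra-by-vertebra model (wrapping
paths, intervertebral translations, ligament nonlinearity).  Surrogate
fidelity numbers on this data therefore certify the pipeline's internal
consistency — that the nets recover the simulator's pose-and-anthropometry
to force mapping — not clinical accuracy on measured subjects.

## Known limitations

* Two lumped articulations cannot localize deficits to individual
  intervertebral levels; the assessment is screening-level by design.
* Straight-line muscle paths misestimate moment arms at extreme poses
  relative to wrapped paths; the feasibility-checked default amplitudes
  stay inside the well-behaved range.
* The frame-sequential reading of the rate term makes forces weakly
  history-dependent (sub-percent at the default λ₂); a joint-horizon
  solve would remove this at much higher cost.
* The best-match search scans the database linearly; for very large
  model libraries an index over envelope descriptors would be needed.
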