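# Methods

## The model

`jawlever` implements a static-equilibrium lever model of bilateral biting
in mammals, built for comparative functional morphologists working from
dissection data.  The jaw is a rigid body rotating about the mediolateral
axis through the centre of the condylar process; each masticatory muscle
pulls the mandible along the line from its insertion centroid towards its
cranial origin centroid.  The chain per muscle *i* is:

1. **PCSA** — `PCSA_i = MM_i / (FL_i · d_M)` with preserved mass `MM` (g),
   mean fibre length `FL` (converted mm → cm) and muscle density `d_M`
   (g·cm⁻³).  PCSA is reported on the *preserved* mass, as dissection
   tables conventionally are.
2. **Maximum 3D force** — `F3Dmax_i = F_MS · MM_i · c_mass / (FL_i · d_M)`,
   i.e. the specific tension `F_MS` (N·cm⁻²) applied to the fresh-mass
   PCSA, where `c_mass` compensates preservation mass loss.
3. **Sagittal projection** — `F2Dmax_i = F3Dmax_i · sin φ_i`, where `φ_i`
   is the angle between the 3D action line and the mediolateral axis.
   Mediolateral force components cancel between the two sides in bilateral
   biting and exert no moment about the rotation axis.
4. **Moment balance** — `R_i = D_IC_i · sin θ_i · F2Dmax_i / D_CBP`:
   in-lever (condyle→insertion, sagittal plane) times the force component
   perpendicular to it, divided by the out-lever (condyle→bite point).
5. **Bilateral sum** — `Fcalc = 2 · Σ R_i` over jaw-*closing* muscles.
   Whether a muscle closes is decided by the sign of its computed moment
   about the condyle, not by a name list; muscles with opening moments
   (the digastric by anatomy, and in the worked example the lateral
   pterygoid by geometry) are reported as excluded.

Opening the jaw is modelled as rigid rotation of the mandibular landmarks
(insertions, bite points) about the condyle; all angles are re-derived
from coordinates after every rotation step, since the 3D action vectors
change as the insertions move.  Sweeping the gape in 0.5° steps and
recomputing `Fcalc` yields a force–gape profile whose peak defines the
optimal gape.  The default sweep stops at the first decrease (valid for
unimodal profiles); `full_sweep` scans to `max_gape` (default 60°).
Plateaus break ties to the smallest gape.

Because every step is linear in `F_MS`, the specific tension that matches
an in vivo bite force has the closed form
`F_MS* = F_MS_ref · F_alive / Fcalc(F_MS_ref)`; an iterative bisection
mode (bracket 0.1–200 N·cm⁻², force tolerance 0.001 N) mirrors the
operational increase/decrease procedure and agrees by linearity.

## Constants and defaults

| constant | default | units | note |
|---|---|---|---|
| muscle stress `F_MS` | 30 | N·cm⁻² | classical mammalian specific tension; refit by calibration |
| density `d_M` | 1.0518 | g·cm⁻³ | head-muscle value; 1.0597/1.0564 (limb), 1.0582 (masseter) documented alternatives |
| mass correction `c_mass` | 1.692 | – | preserved→fresh factor for ~40.9 % formalin/ethanol mass loss |
| gape step | 0.5 | deg | sweep resolution |
| bilateral factor | 2 | – | mirror-symmetric biting; no per-side asymmetry |

No force–length (sarcomere stretch) effect is modelled: `F3Dmax` is
gape-independent, only geometry changes with opening.  Pennation-angle
(RPCSA) corrections are deliberately out of scope.

## Coordinate and sign conventions

Skull-fixed frame: x anteroposterior (+anterior), y dorsoventral
(+dorsal), z mediolateral; the sagittal plane is x–y.  Positive rotation
opens the jaw (anterior points move ventrally).  Moments about the
condyle are signed opening-positive, so jaw closers have negative moments;
`θ` is insensitive to the (unfixed) direction convention of the lever
vector because only `sin θ` enters the force, while the signed moment
disambiguates openers from closers.

## The worked example and its geometry-free mode

The package ships the dissection tables of two adult male *Marmosa
murina* specimens (M1496, M2851: 13 masticatory muscles each) together
with the closed-mouth model table of M2851 and the in vivo bite forces at
the incisors and the last lower molar (m4).  The original landmark
coordinates were never published, so absolute lever distances are
unrecoverable; the planar ("geometry-free") mode therefore accepts
tabulated `(F3Dmax, φ, θ, D_IC)` values directly, with out-levers supplied
as scalars and openers declared explicitly.  The shipped fixture
back-solves the in-levers from the printed last-molar resultants at a
conventional `D_C−m4` = 10 mm and uses the incisor/molar out-lever ratio
2.337 implied consistently by the printed resultant columns; every
downstream quantity depends only on these ratios.

## Synthetic geometries

`generate_geometry` inverts the angle derivation: given per-muscle
targets `(φ, θ, D_IC)` and out-levers, it places each insertion at its
in-lever distance from the condyle in the sagittal plane and the origin
along the direction that realises `(θ, φ)`, at a fixed insertion→origin
distance.  At zero noise the round trip through action-line derivation
recovers every target to floating-point accuracy; with noise, landmarks
are jittered isotropically with standard deviation `noise_sd` × the mean
lever/out-lever scale.  All randomness flows through one seeded
`numpy` generator.

The insertion→origin distance is unconstrained by a closed-mouth table
but controls how fast action lines reorient during opening (the action
direction turns by roughly `D_IC / origin_distance` per degree of
rotation), and hence where the force–gape profile peaks.  The generic
default is 10 mm.  For the worked-example lift
(`reference.reference_geometry`) we use 30 mm — the placement direction of
the insertions is provably irrelevant (it amounts to a global rotation of
the construction), leaving this single scalar free — because it
reproduces the published force–gape behaviour of the specimen: a
single-digit optimal gape (6.0° modelled vs 6.5° reported) with a ~0.6 %
force gain over closed mouth.  This is a reconstruction, not the true
anatomy; opened-jaw results on the fixture should be read as
qualitative.

`generate_architecture` draws log-normal masses (median 0.02 g, σ = 0.6)
and fibre lengths (median 3.5 mm, σ = 0.25), centring the derived PCSAs
on the 0.01–0.15 cm² band observed in mouse-opossum-sized jaws.  The
generator emulates scale and spread only — no correlation structure
between muscle size and position, no allometry, no digitisation error
model — so passing tests demonstrate pipeline correctness, not anatomical
realism.

## Sensitivity analysis

`run_sensitivity` scales one scalar of one muscle at a time by
(1 ± fraction) (default ±5 %) and records the percent change of `Fcalc`:
the six parameters are in-lever, θ, mass, fibre length, φ, and the
out-lever as it enters that muscle's term.  Mass and fibre length act on
`F3Dmax` multiplicatively (∝ MM/FL), so the analysis runs on the planar
model.  Structural identities follow from the sum-of-terms model and are
asserted to 1e-9: factor parameters shift the total by exactly ± fraction
× the muscle's force share `2·R_i/Fcalc`; pure denominators (fibre
length, per-muscle out-lever) produce identical columns; mass
sensitivities sum to the full perturbation.  Angle perturbations are
multiplicative on degrees (θ → 1.05·θ), so their effect follows
`sin(1.05θ)/sin(θ) − 1` and can flip sign past 90°.  Perturbations that
leave the [0°, 180°] domain are flagged, not raised.  The default
evaluation is at closed mouth; the published per-entry percentages of the
original study are not reproducible because its evaluation configuration
(gape/geometry) is unstated, so only these structural properties are
asserted.

## Numerical choices

* Angles at interfaces in degrees, radians internally; the sagittal
  projection uses the `sin φ` form, which is numerically stable where the
  radical form cancels.
* Degenerate geometries (zero-length action vector, purely mediolateral
  pull, insertion on the condyle in the sagittal plane) raise a dedicated
  error naming the muscle and gape; relative threshold 1e-12.
* Gape axes are computed as exact step multiples (no accumulated float
  drift); rotation composition is exact to 1e-12 per step.
* Printed-style rounding (3 decimals N, 2 decimals degrees/percent) is
  applied only in the text reports; CSV/JSON carry full precision, and
  reruns of identical configurations are byte-identical.

## Problem sizes

The test suite and the reproduction script run on the worked-example
scale: 13 muscles × 2 specimens, 12-muscle equilibrium models, gape grids
of ≤ 120 steps (0.5°) and 3 000 steps for the 0.01° brute-force oracle,
100 random landmark sets for the cross-product oracle, and 1 000 draws
for the architecture-distribution check — comfortably desk-scale.

## Known limitations

* Pure rotation about a fixed condylar axis: no temporomandibular
  translation, no joint reaction decomposition, no unilateral biting.
* No force–length or activation dynamics; tetanic contraction of all
  closers simultaneously.
* Bilateral symmetry is assumed exactly (factor 2).
* The worked-example geometry above 0° gape is a constrained
  reconstruction, not measured anatomy.
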