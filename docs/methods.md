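# Methods

## Idealized helix geometry

All phase calculations assume straight, torsionally uniform B-DNA:
position *p* (bp, possibly half-integer) maps to azimuth
(θ₀ + p·τ) mod 360°, with twist τ = 36.0°/bp (10.0 bp/turn) and rise
3.4 Å/bp by default. Both GAL4 and ZEBRA bind without appreciably bending
their sites and neither binds cooperatively, so a rigid linear model is
the appropriate zeroth-order geometry; sequence-dependent twist/roll and
protein-induced bending are deliberately out of scope. 36.0°/bp was chosen
over 10.4–10.5 bp/turn alternatives because it places the opposite-face
spacers of a 17-bp-site pair on the 0–48 bp grid at exactly
{8, 18, 28, 38} bp, the observed optimum spacings; both twist and site
lengths are configuration parameters.

Coordinates are 1-based and inclusive; a site's center is
start + (length−1)/2 and phases are evaluated between centers, matching
the center-to-center convention (spacer + mean site length). The folded
phase is min(δ, 360−δ) ∈ [0°, 180°]. A pair is *same-face* when its
folded phase is ≤ 90° and *opposite-face* above 90°; the tie at exactly
90° resolves to same-face so the partition is exhaustive. Reverse
orientation of a site does not move its center, so strand is ignored.
Overlapping sites are phased with a warning rather than rejected, which
keeps design exploration fluid.

**Even spacing.** k sites are called evenly spaced when every circularly
consecutive azimuth gap is within a tolerance of 360/k. With integer
center-to-center distances at 36°/bp, achievable gaps are multiples of
36°, so the best three-site approximation to 120° spacing is
{108°, 108°, 144°}; the default tolerance of 25° is chosen to admit such
integer-constrained designs while still rejecting collapsed arrangements
(all gaps equal to within 25° of 120° fails for {0°, 0°, 360°}-type
layouts by a wide margin).

## Structural layer

PDB reading/writing goes through biotite (wwPDB v3.3 fixed columns;
first model only). Superposition is a standard Kabsch fit: center both
matched point lists, SVD of the covariance, proper-rotation sign fix,
RMSD of the fitted points. Collinear point sets leave rotation about the
common axis undetermined and are reported as numerical errors rather
than silently resolved. Which atoms crystallographers' tools matched in
comparable workflows is generally unstated, so the reference atom set is
explicit everywhere (fixtures use one phosphate-like pseudo-atom per
nucleotide) and is reported alongside each fit.

The *transverse extent* of a complex is the maximum pairwise distance of
its atoms after projection onto the plane perpendicular to the helix
axis — the width a native gel "sees". For two spherical factor clusters
of radius ρ at radial distance R and azimuth separation φ the analytic
value is 2ρ + 2R·sin(φ/2), minimal for same-face and maximal for
opposite-face binding; the atom-based and analytic routes agree on the
generated fixtures and the quantity is invariant to rotation about, and
translation along, the axis.

## EMSA detrending

Across a spacer series the probe grows with the spacer, so complex
mobility confounds probe length with complex shape. The free-probe lanes
define a least-squares marker line of log(migration) on probe length
(natural log; the base only rescales residuals). Saturated-complex
residuals from this line isolate the shape effect: more negative =
slower than a free probe of that length = wider complex. Local minima of
the residual series mark opposite-face spacings.

The minimum finder implements an explicit near-tie rule: scanning left
to right, maximal runs of consecutive points whose values stay within
`tie_epsilon` of the running extremum are collapsed to one candidate,
reported at the run's middle lane (lower index for even runs); a
candidate is a minimum only when strictly below both flanking values,
and series endpoints are never reported. `tie_epsilon` defaults to 2% of
the residual range, a concrete operationalization of "nearly equal"
lanes. Peak detection on activation curves is the same routine applied
to the negated series, so the two assays share one extremum contract.

## Activity analysis

Per-replicate activity is firefly/Renilla; rows with non-positive
Renilla (failed transfection control) are rejected with a warning.
Condition means, SDs and n feed the curve-level analyses. The periodic
fit uses A(s) = e^(−λs)·[b + a·sin²(π(s+c)/P)]: sin² gives one peak per
period P with a nonnegative modulation, and the exponential keeps the
attenuation positive (a linear-decay variant would admit negative
predictions). P is found by a grid scan over 8–13 bp with the remaining
parameters fitted per trial period, followed by local refinement with P
free; flat curves are returned flagged as non-converged rather than
raising. Template comparisons report the fold change of means with a
Welch t test as a descriptive aid (no multiple-testing correction is
applied anywhere — the template panels are small and the comparisons
confirmatory). Titration dominance is evaluated on per-dose means only,
mirroring how concentration controls are read in practice.

Synergy is declared when the two-site/one-site activity ratio strictly
exceeds 2, the additivity bound for independently acting sites.

## The equilibrium steric-hindrance model

Binding of activators is modeled as a thermodynamic equilibrium over
occupancy states of the promoter's activator sites. Each bound site
contributes an association weight K (proportional to activator dose);
each simultaneously bound pair pays a steric penalty:

    weight(state) = ∏_{i bound} K · ∏_{i<j bound} exp(−w·g(φᵢⱼ)·e^(−dᵢⱼ/ξ))

with angular kernel g(φ) = cos^(2k)(φ/2) (1 at phase 0, exactly 0 at
180°) and center-to-center distance dᵢⱼ in bp. Expected recruitment sums
over states: each bound activator contributes
r·e^(−d_TATA/ξ_r), reduced by a factor (1 − ρ·g(φᵢⱼ)·e^(−dᵢⱼ/ξ)) per
co-bound neighbour — a same-face neighbour occludes the activator's
interaction surface, an opposite-face neighbour does not. Reporter
output follows a Hill response A = A_basal + A_max·R^m/(R50^m + R^m),
whose superlinearity at small R converts a near-doubling of recruitment
into the greater-than-twofold synergy of two-site templates. Occupancy
is enumerated exactly (≤ 12 sites); a Metropolis sampler over the same
weights serves as an independent cross-check in the tests.

The TATA-bound pre-initiation complex is a fixed landmark: it is phased
and classified like any site and anchors the recruitment distance
attenuation, but it takes no part in the pairwise steric terms. This is
deliberate — the distal activator's phase to the TATA complex is offset
by a constant 162° from its phase to the proximal activator, so a
steric TATA coupling would anti-correlate with (and at plausible
strengths overturn) the activator-pair phase dependence, contradicting
the observation that the activator–TATA phase relation leaves the effect
untouched.

### Default parameters (GAL4 configuration)

| parameter | default | meaning |
|---|---|---|
| K | 2.0 | association weight per site at unit dose (dimensionless) |
| w | 2.0 | steric-hindrance strength |
| ξ | 250 bp | steric interaction range |
| k (sharpness) | 1.6 | angular kernel exponent; k=1 is a plain cos² falloff |
| r | 0.2 | recruitment per unhindered bound activator |
| ρ | 0.5 | maximal recruitment interference |
| ξ_r | 800 bp | recruitment decay scale with TATA distance |
| R50, m | 1.0, 3 | Hill half-saturation and coefficient |
| A_basal, A_max | 0.05, 1000 | reporter floor and span |

No quantitative magnitudes exist for hindrance or recruitment in this
system; the defaults are calibration choices, fixed once so that the
noise-free model reproduces the qualitative and quantitative anchors of
the phenomenon simultaneously: activation peaks exactly at
{8, 18, 28, 38} bp with the global maximum at 8 bp; a minimum
two-site/one-site ratio of 2.03 (> 2 at every spacer); a ~2.5-fold
difference between the 27-bp and 21-bp center-to-center designs at a
26-bp TATA offset; the 27-bp design above the 21-bp design at a 22-bp
offset likewise; three- and four-site alternating/evenly-spaced designs
above their all-same-face counterparts; and activity monotone in dose at
every spacer. The long steric range (ξ = 250 bp) reflects that phase
modulation is observed undiminished across the whole 0–48 bp series; it
also gives the curve non-degenerate troughs, which is what makes peak
detection stable under measurement noise. Two structural choices differ
from the most obvious minimal model and deserve note: the Hill
coefficient is 3 rather than 2 because with m = 2 the two-fold
196-vs-193-type contrast and an everywhere->2 synergy floor are
mutually exclusive (the fold is bounded by 2^m divided by the synergy
floor), and the angular kernel is sharpened (k = 1.6) because a plain
cos² leaves too much hindrance at φ = 108°, the folded phase of the
27-bp "opposite-face" design. Both knobs are exposed and k = 1, m = 2
recover the simpler forms.

### ZEBRA configuration

The ZEBRA series shows a single activation peak at 8 bp spacing rather
than a repeating comb. The packaged ZEBRA parameter set (K=1, w=150,
ξ=3 bp, k=1, r=1, ρ=0.5, ξ_r=20 bp, m=3) embodies that as a
short-range, high-amplitude clash — strong at the 15-bp center-to-center
distance of the 8-bp spacer, negligible by 25 bp — combined with steep
recruitment attenuation, so the 18-bp spacer (also geometrically
opposite-face) no longer rises above its neighbours.

## Synthetic data

The generators emulate the statistical structure the analyses assume:

- **Activity tables** — triplicate firefly/Renilla counts per condition;
  both channels carry independent unit-mean lognormal noise with CV 0.10
  by default, so the normalized ratio has CV ≈ 0.10·√2. At cv = 0 the
  normalized replicates equal the simulator's expectation exactly.
- **Gel tables** — log free-probe migration exactly linear in probe
  length (intercept 5.0, slope 0.004/bp); complex lanes further retarded
  by 0.002 log-units per Å of transverse extent (clusters of 15 Å radius
  at 30 Å from the axis — a GAL4-dimer-scale footprint), plus Gaussian
  log-noise (sd 0.005). Noise-free, the detrended minima sit exactly on
  the opposite-face spacers.
- **PDB fixtures** — axis pseudo-atoms plus one deterministic spherical
  shell of pseudo-atoms per bound factor at its site's azimuth.
- **Template FASTA** — motifs (17-bp GAL4 palindrome, 7-bp ZIIIB, 8-bp
  TATA) embedded in a fixed neutral filler, with a 1-based coordinate
  sidecar.

One integer seed fans out deterministically into per-generator
substreams; identical seeds give byte-identical outputs.

What the generators do *not* emulate: real replicate noise magnitudes
(unknown; CV is a free parameter), partial-occupancy EMSA bands (only
the saturated complex is modeled), gel image artifacts, sequence effects
of the filler, chromatin context, and DNA looping. Passing tests
therefore demonstrate that the analysis stages are correct and mutually
consistent under the model's assumptions, not that the model is a
complete account of the biology.

## Numerical choices and degenerate inputs

- Extremum ties: middle of the near-equal run, lower index for even
  runs; endpoints never reported.
- Face-class tie at exactly 90°: same-face.
- Periodic fit: non-convergence and flat curves are flagged results, not
  exceptions; the period search is bounded to 8–13 bp.
- Kabsch: < 3 points or count mismatches are input errors; collinear
  sets are numerical errors; rotations are checked proper (det = +1).
- Occupancy enumeration is capped at 12 sites (4096 states).
- Zero/negative Renilla rows and lanes without complex migration are
  skipped with warnings, never silently imputed.

## Known limitations

- The geometry is phase-only: it predicts *which* spacers are optimal
  but not activation magnitudes; magnitudes come from the calibrated
  equilibrium model.
- The 191-style (evenly spaced) and 192-style (alternating) three-site
  designs agree only to ~40% in the model, a coarser match than their
  experimental equality.
- The overall distance attenuation of activation is gentle under the
  default calibration (the 36-bp peak reaches ~0.68 of the 8-bp peak).
- Real crystal structures are supported through plain PDB files but all
  shipped tests run on generated fixtures; no structure is downloaded.
- Problem sizes throughout (25-point spacer grids, triplicates, 10⁵-step
  Metropolis checks, 100-fit recovery studies) are chosen so the entire
  suite runs in about a minute on one core.
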