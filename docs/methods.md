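# Methods

## Physical model

Each sample is treated as an ensemble of *N* identical polar molecules,
each carrying an effective bound charge *Q* (coulomb) of mass *M* (kg),
suspended in buffer. Three forces act on the charge: a harmonic binding
force (chemical bonding, natural angular frequency ω₀), a viscous damping
force (buffer drag, rate γ per second), and the driving force of the probe
field *E₀ e^{−iωt}*. Solving the driven-damped oscillator and summing the
per-molecule dipoles gives the relative permittivity

    ε_r = 1 + S (ω₀² − ω²) / ( ε₀ [ (ω₀² − ω²)² + (γω)² ] ),   S = N Q² / M.

This is the dispersive (real) part of a single Lorentz resonance; the
package deliberately models one oscillator per sample — no Debye/Cole–Cole
relaxation spectra, no multi-oscillator fits, no atomistic detail.

All internal frequencies (ω, ω₀, γ) are angular, rad/s. Reported
frequencies are cyclic (Hz/MHz = ω/2π) and labelled as such. Mixing the
two conventions changes results by 2π ≈ 6.3×; the package never does.

## Inversion

With the detuning x = ω₀² − ω², the forward map inverts exactly as a
quadratic:

    x² − B x + (γω)² = 0,   B = S / (ε₀ (ε_r − 1)),
    x± = [ B ± √(B² − 4γ²ω²) ] / 2,   ω₀² = x + ω².

Properties that drive the implementation:

- ε_r ≤ 1 is degenerate (B undefined or negative); it raises an explicit
  error. Rows with mean ε_r ≤ 1 are skipped by the sweep with a logged
  diagnostic.
- For ε_r > 1 both x-roots are positive (sum B > 0, product γ²ω² > 0), so
  ω₀ > ω always. With a 6.41 GHz drive, recovered natural frequencies are
  GHz-scale by construction.
- When B² < 4γ²ω² the roots are a conjugate complex pair. They are
  returned flagged (`kind="complex"`), never replaced by magnitudes.
  Substituting either complex root back into the forward map still yields
  exactly ε_r, because the quadratic identity x² + γ²ω² = Bx makes the
  imaginary parts cancel; the round-trip check therefore holds for every
  root, real or not.
- The *selected* root is the smaller real root when real roots exist (the
  gentler oscillator; the branch choice is otherwise arbitrary and both
  roots are always reported). With no real root, the complex root with
  non-negative imaginary detuning is selected and flagged; per-molecule
  magnitudes computed from it use moduli and carry a diagnostic, and the
  radar summary excludes such rows from its frequency entry by default.

Numerical care: each root object stores x exactly as produced by the
quadratic (the smaller root via x_lo = (γω)²/x_hi for stability).
Recomputing x from ω₀ as ω₀² − ω² cancels catastrophically when
x ≪ ω², so `forward_permittivity` uses the stored detuning when handed a
root object. The bare-scalar path is accurate whenever x ≳ 10⁻⁴ ω², which
the tests exercise separately.

An `as_printed` inversion mode evaluates a historically typeset
discriminant variant, (B + 2ω²)² − 4(B + 2ω²)(ω⁴ + γ²ω² + Bω²), verbatim
for audit. Its roots do not invert the forward map and are flagged
`non-round-trippable`; the consistent quadratic is the default because
round-trip consistency is the only testable contract.

## Polarization response and current density

The complex response at time t is

    P̃(t) = S E₀ (x + iγω) / (ε₀ (x² + γ²ω²)) · e^{−iωt},

a susceptibility-scaled field response (per-volume units are not fixed by
the model inputs; the label is deliberate). The polarization current
density is defined as J = dP/dt of the real part:

    J(t) = S E₀ ω / (ε₀ (x² + γ²ω²)) · ( γω cos ωt − x sin ωt ),

which matches a centred finite difference of P to better than 10⁻⁶
relative (tested over 100 random parameter draws). An `as_printed` mode
retains an extra (ω₀² − ω²) prefactor and omits the ε₀ factor, again for
audit only. Time-dependent quantities are reported at t = 1 µs, the order
of protein relaxation times.

## Damping calibration

γ is an empirical parameter, calibrated so that the per-molecule dipole
amplitude — charge times displacement amplitude,

    p(γ) = (Q²/M) E₀ / √(x(γ)² + (γω)²),

with x re-solved from the inversion at each trial γ (smaller real root) —
matches the literature dipole moment (369 D insulin, 150 D papain;
1 D = 3.33564×10⁻³⁰ C·m). On the real-root domain γ ∈ (0, B/2ω), p(γ) is
strictly decreasing, so a bracketed Brent search on log₁₀ γ over
[10⁻³, 10¹⁵] s⁻¹ (intersected with the real-root domain) is used,
tolerance 10⁻⁸ relative, deterministic. Planted-γ targets are recovered
to better than 10⁻⁶ relative.

For the packaged insulin/papain parameters the literature targets are
*unreachable*: with N from concentration × volume / M, the achievable
dipole range bottoms out near 10⁻²⁰ C·m, seven orders above the ~10⁻²⁷
C·m targets. The calibration then returns the nearest-achievable γ (the
real-root boundary, approached from inside) with `converged=False` and an
explicit no-solution message — never a silent clip. Downstream results
carry this diagnostic. Consequence: at temperatures warmer than the
calibration point (and for mixtures with diluted strength), B shrinks
below 2γω and the inversion yields flagged complex pairs; the round trip
still holds exactly, but no real MHz/GHz frequency is claimed for those
rows. γ is calibrated once per protein at the coolest measured temperature
of its most concentrated pure sample and held fixed across the sweep;
`recalibrate_per_temperature=True` recalibrates pure samples per
temperature instead.

## Mixture rules and molecule counts

    N_i = c_i V_i / M_i          (pre-mix concentration, contributed volume)
    γ_mix = Σ γ_i V_i / Σ V_i    (volume-weighted mean, any k ≥ 1)
    S_mix = Σ N_i Q_i² / M_i     (additive strength)

Component mass is conserved on mixing, hence pre-mix concentrations.
Species flagged `inert` (ZnO micro/nanoparticles: near-zero net charge,
mass far above the proteins') contribute zero strength and are excluded
from the damping average as well — numerator *and* denominator — by
default; `include_inert_in_damping=True` weights them in, in which case
they need a γ of their own. The flag is per-species, not hard-coded to
ZnO.

## Replicate aggregation

Means are arithmetic per (sample, temperature) or (sample, quantity).
Spread is half the max−min range for two runs (matching two-run error
bars) and the sample standard deviation (ddof = 1) for three or more
(replicate zeta-potential tables). Group values are sorted before
reduction so aggregation is exactly permutation-invariant.
`printed_mean` renders a mean at a table's printed precision by
truncation toward zero (with a guard for values already exact at that
precision) — the convention under which the packaged replicate table's
aggregate cells reproduce exactly.

## Verification scan

The pumped-frequency absorption experiment is simulated with the
Lorentzian consistent with the package's oscillator,

    A(ω) = P_pump (γω)² / ( (ω₀² − ω²)² + (γω)² ),

which absorbs the full pump power exactly on resonance. The lineshape is
a modelling choice of this package (the experiment fixes only "absorption
peaks at the natural frequency"). Additive Gaussian receiver noise is
seeded and deterministic; the result is clipped to [0, P_pump], slightly
distorting the noise distribution at the peak (documented, immaterial for
peak location). Detection refines the grid argmax by three-point parabolic
interpolation; flat scans and boundary maxima (e.g. monotone ramps) raise
a no-peak error. dBm→W uses the standard 10^(p/10) mW conversion
(−50 dBm = 10 nW); equating −50 dBm with tens of microwatts is a unit
slip, so no as-printed variant exists here.

## Synthetic data

The generator emulates the study conditions the analysis assumes:
temperature sweeps 30–55 °C in 5 °C steps, two replicate runs by default,
and a strictly monotone ω₀(T) (linear in T by default — unfolding drives
the frequency one way). Noise is multiplicative on ε_r (spread scales
with magnitude in this kind of measurement; additive mode available),
with a hard floor at 1 + 10⁻⁶ and a clip counter that is logged and
returned, zero at zero noise. Default recovery checks use γ = 5×10⁹ s⁻¹
and ω₀ from 1.55ω down to 1.30ω, giving permittivities of realistic tens;
the bias test uses 5% noise with 50 runs. What passing recovery shows: the
pipeline is an exact inverse of its own forward model under the assumed
noise. What it does not show: correctness of the single-oscillator
idealization for real protein solutions, probe-geometry effects, or any
frequency dependence of γ.

The packaged `literature_fixture()` carries the measured permittivity
series (insulin 68→370, papain P1 27→31, P2 24, P3 22, insulin+ZnO
spherical 40→167, tetrapodal 95→351 over 30→55 °C) and species constants,
so every stage runs end-to-end without downloads.

## Problem sizes

Default verification settings — 10⁶-point oracle grids × 100 draws,
1000-draw mixture invariants, 200 noisy scans, 50-run synthetic sweeps —
keep the whole suite in single-digit seconds on one CPU while leaving the
oracle far denser than the features it must resolve.

## Known limitations

- Single Lorentz oscillator per sample; no relaxation-spectrum fitting.
- The per-molecule dipole definition (Q × displacement amplitude) is the
  package's choice of calibration observable.
- γ is temperature-independent by default.
- Per-volume normalization of P̃ and J_P is nominal (susceptibility-scaled
  field response), as the model inputs do not fix it.
- MHz-scale natural frequencies cannot arise from this model for ε_r > 1
  under consistent SI units (ω₀ > ω is forced); the package exposes the
  `as_printed` audit modes rather than guessing an alternative numeric
  path.
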