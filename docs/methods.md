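# Methods

This note documents the models, conventions, and numerical choices behind
`slimim`, and what the synthetic-data generator does and does not emulate.

## Instrument geometry

The track model is purely arithmetic: a traveling-wave cycle spans
`pads_per_cycle` pads (default 8), so the wavelength is
λ = pitch × pads_per_cycle = 1.125 mm × 8 = 9.0 mm, and switching
frequencies of 5–25 kHz correspond to wave speeds of 45–225 m/s
(speed = f·λ). The electrode-set count uses floor division of the path
length by λ — a partial set at the track end is not counted — giving 1444
sets per conveyor row over 13 m; the total conveyor-pad count multiplies by
pads per cycle and the number of parallel rows (5), and is exposed per-row
with the row count as an explicit multiplier because published set counts
do not state whether they are per-row totals. Waveform snapshots assign
electrode *i* the drive signal delayed by *i* phase steps (45° for 8-pad
sets); the square drive is a two-level ±A/2 pattern (4 pads high, 4 low)
advancing one pad per switching step.

## Transport model

Mobility comes from the Mason–Schamp relation in the low-field limit with
the ion mass taken as m/z × z (electron and adduct mass folded into m/z):

    K = (3 z e / 16 N) · sqrt(2π / (μ k_B T)) / Ω

at the configured gas state (N₂, 2.5 Torr; 300 K by default — the
operating temperature is not tightly controlled on such instruments and
enters only through K and D).

The drive physics is a roll-over law for a sinusoidal traveling potential.
Defining the wave ratio c = K·E_max/v_wave with E_max = η·π·A/λ:

* c ≥ 1: the ion surfs, locked to the wave at exactly v_wave. Surfing ions
  co-arrive and carry no mobility information.
* c < 1: the ion slips over successive crests; its cycle-averaged speed is
  v̄ = v_wave·(1 − √(1 − c²)), monotone in c.

Two deliberate model choices here:

* **The roll-over law itself** is the standard idealized result for drift
  in a moving sinusoidal potential. It is the simulation backbone chosen to
  reproduce the *qualitative* surfing→drift transition; it is a model
  choice, not an experimentally fitted transport equation.
* **Field utilization η (default 0.285).** Surface-electrode potentials
  decay away from the board plane, so ions traveling mid-gap between the
  two boards feel only a fraction of the ideal π·A/λ field. With η = 1
  every realistic tune-mix ion would surf at all surveyed speeds. η = 0.285
  was fixed once so that the surfing→drift transition falls in the
  experimentally reported wave-speed range for both ends of the m/z ladder
  simultaneously (m/z 622 separating near 225 m/s with a ~290 ms arrival;
  m/z 2722 near 90 m/s with a ~540 ms arrival); it is configurable in
  `TransportParams`.

A square drive is represented by its sinusoidal fundamental, whose
amplitude is 4/π larger; square operation therefore surfs more readily and
separates a smaller share of grid cells — the direction observed
experimentally.

Arrival time is t = L/v̄ + t₀ with t₀ = 5 ms by default for the non-IM
portions of the flight path (transfer optics, funnels). The companion
ion-speed fraction (L/(t − t₀))/v_wave recovers, e.g., 33.3% and 66.7% of
the wave speed for arrivals at 3× and 1.5× the surf-only time.

## Peak widths

Three variance components add in quadrature (as time-domain fwhm):

1. **Diffusion**: spatial σ² = 2·D·t_drift with D = k_B·T·K/q, converted
   to time through v̄; grows as √t at fixed speed.
2. **Slip dispersion**: σ² = F·λ·v_wave·√(1−c²)·t_drift with F = 1.5×10⁻³
   (a Fano-like factor). Roll-over is a quasi-periodic stochastic process;
   treating the slip count as weakly over-dispersed gives a variance term
   that scales with wave speed, vanishes in the surfing limit (c → 1), and
   degrades resolving power at long residence times. Pure diffusion alone
   cannot produce the observed late-time resolving-power decline under the
   roll-over law — the time→CCS slope flattens at long times and exactly
   compensates the √t diffusive growth.
3. **Instrument floor**: fixed 3.5 ms fwhm, dominated by the ion-gate
   release width (~10 ms accumulation gates release sub-gate packets) and
   post-IM transfer broadening.

F and the floor were fixed together, once, in a single design exploration
against three structural constraints the generator is required to satisfy:
mid-panel resolving powers of 200–320 at 180 m/s / 40 V_pp, maximum median
R_p inside the 200–700 ms band, and medians below 200 beyond 1.2 s. They
were not revisited afterwards.

## Synthetic panel and traces

The tune-mix panel is eight singly charged ions at m/z 622…2722. Published
drift-tube reference CCS values for these calibrants are not redistributed;
the packaged ladder is **synthetic** — CCS = 6.9·(m/z)^0.525 rounded to
0.1 Å², a smooth strictly monotone curve with realistic magnitudes
(202–439 Å²). Any user-supplied table overrides it.

Traces are sums of Gaussians at the analytic arrival times and widths
(equal heights of 1000 counts by default), with optional noise: Gaussian
(σ = 1% of the tallest peak by default) or Poisson shot noise, from a
single seeded generator; equal seeds give bit-identical traces. Sampling
is 0.5 ms by default and the window auto-covers every peak ±6 fwhm.

What the generator does *not* emulate: ion losses and transmission
efficiency, peak asymmetry/tailing, space-charge effects, wave-amplitude-
dependent ion heating, chemical backgrounds, and detector saturation.
Passing tests therefore demonstrate the correctness and internal
consistency of the analysis chain under idealized Gaussian statistics, not
instrument-level accuracy on real data.

## Peak fitting and separation metrics

Fits are nonlinear least squares (lmfit) of n Gaussians plus a constant
baseline on the raw trace — no smoothing. Initial guesses come from
prominence-ranked apex detection (or user windows); peaks are returned
sorted by centroid with ties broken by descending height; non-convergence
flags the peak rather than dropping it. Per-peak R² is evaluated within
±1.5 fwhm.

The time→CCS conversion between two peaks of known CCS is locally linear:
slope = ΔCCS/Δt across the pair. This is applied only over the width of a
peak; the global arrival-time/CCS relation of traveling-wave separations
is nonlinear, which is why calibration (below) uses nonlinear regression.
R_p(CCS) = CCS/(|slope|·fwhm); for multi-peak spectra the mean CCS of the
peaks is the numerator and the reported value averages over peaks
(average-CCS convention). In the benchmark grid the slope partner is the
next-highest-m/z ion, falling back to the next-lowest at the ladder end.

Two-peak resolution uses the Gaussian baseline-width convention,
R_pp = 2·Δt/(1.699·(fwhm₁+fwhm₂)); the 1.699 factor is a documented,
swappable choice made because it places R_pp = 1.5 at baseline separation:
equal Gaussians at R_pp = 1.5 show a 97.8% valley (≈100%), and at
R_pp = 1.1 an 82% valley — matching reported near-baseline readings.
Percent valley uses the *lower* apex as reference (conservative for
unequal-abundance isomer pairs) and requires a true interior local
minimum; merged unimodal pairs report V = 0 with a no-valley flag. ΔCCS%
is referenced to the smaller CCS and reported to one decimal.

## CCS calibration

CCS′ = CCS·√μ/z with μ from m_ion = m/z × z and N₂ (28.0134 Da). Models:
power law a·t^b (scipy `curve_fit`, log-log-seeded) and 2nd/3rd-order
polynomials (`numpy.polyfit`), unweighted least squares on CCS′ against
the *raw* arrival time (no t₀ subtraction — an optional offset exists but
defaults to zero). R² is computed on CCS′; a non-monotone fitted curve
inside the calibration range raises a warning flag. Predictions outside
[min t, max t] require an explicit `extrapolate=True` — polynomial
calibrations extrapolate badly by construction.

On the simulated ladder at 180 m/s / 40 V_pp the third-order polynomial
attains R² ≈ 0.99998 with ≈0.09% mean |bias| versus ≈0.9996 and ≈0.48%
for the power fit — the cubic ranks first, the power law remains the
generalizable (extrapolatable) choice. Because calibration quality varies
with wave speed, `scan_calibration_speeds` sweeps the integer-kHz raster
(5–25 kHz) at 40 V_pp, skips conditions where any calibrant surfs, and
reports per-speed biases; the lowest-bias speed (~144 m/s for the default
panel) keeps every round-trip |bias| below 0.1%.

## Benchmark grid

The default grid is 8 ions × 5 speeds (45–225 m/s) × 3 amplitudes
(30/35/40 V_pp) × 2 waveforms × 3 replicates = 720 records, in long/tidy
form with per-record regime flags; replicate seeds derive deterministically
from the master seed via `numpy` SeedSequence spawn keys, so a run is
byte-reproducible from config + seed. Surfing records carry arrival times
but no R_p. Region summaries bin arrival times (200 ms default) and report
median/quartile R_p per bin; under the defaults the 400–600 ms bin holds
the maximum median (~248) and medians decline below 200 past 1.2 s.

## Problem sizes

The packaged studies run at desk scale by design: 720 grid cells with
single-Gaussian fits (~5 s), 100-replicate noise recovery (~10 s), and
8-point calibration ladders — sizes chosen so the full workflow, including
the acceptance script, completes in well under a minute while exercising
every analysis path.

## Known limitations

* The roll-over law is an idealization; real SLIM transport includes
  field inhomogeneity across the gap, turn effects in the serpentine path,
  and amplitude-dependent heating, none of which are modeled.
* η, the slip Fano factor, and the width floor are effective parameters
  chosen to reproduce regime structure, not first-principles values.
* The synthetic CCS ladder supports method validation only; quantitative
  CCS work requires measured reference values.
* The amplitude ordering of resolving powers near the surfing boundary is
  not asserted quantitatively — only the regime structure is claimed.
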