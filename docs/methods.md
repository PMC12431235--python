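# Methods

## Scope and model structure

`nervecap` computes extracellular signals of peripheral-nerve activity in
three layers:

1. **Fiber layer** (`fiber`): conduction laws (myelinated v = a·d,
   unmyelinated v = b·√d), Gaussian or tabulated AP waveforms V_t(t) with the
   peak pinned at t = 0, the axial prefactor η = πd²σ/4 linking membrane
   potential curvature to membrane current, and the 1/d stimulus-threshold
   law.
2. **Signal layer** (`sensitivity`, `sfap`): lead fields Φ(l) per unit
   recording current, and the reciprocity convolution
   S(t) = (η/v)(∂²V_t * Φ(l_init + v t)). A brute-force point-source
   summation of discretized membrane currents serves as an independent
   cross-check in a homogeneous medium, and closed forms exist when both AP
   and lead field are Gaussian.
3. **Population layer** (`recruitment`, `ecap`, `synth`, `inverse`):
   titration-based recruitment curves rescaled to diameter via the 1/d
   threshold law, diameter-weighted exposure functions, eCAP assembly by
   linear superposition, and gamma-parameter recovery by pattern search.

## Key parameters

| Parameter | Meaning | Default | Rationale |
|---|---|---|---|
| a | myelinated velocity coefficient | 4.3·10⁶ s⁻¹ | fit of linear law to a myelinated fiber model |
| b | unmyelinated velocity coefficient | 470 m^0.5 s⁻¹ | fit of square-root law to a C-fiber model |
| w_V | Gaussian AP width (σ) | 5·10⁻⁵ s (myel.) / 2·10⁻⁴ s (unmyel.) | Gaussian fits to the two AP shapes |
| w_φ | Gaussian contact lead-field width | 1 mm | typical cuff-contact extent along the fiber |
| σ_τ | axial conductivity | 1 S/m | pure amplitude scale; not constrained by shape data |
| V_p | AP peak | 100 mV | typical transmembrane excursion; amplitude scale only |
| d₀ | titration reference diameter | 4 μm (myel.) / 0.8 μm (unmyel.) | reference populations used for threshold titration |
| diameter grid | shared support | 2000 points on 0.1–15 μm | resolves recruitment cutoffs; doubling changes signals by <0.1% |
| time grid | eCAP sampling | 10 μs step, 0–25 ms | resolves w_V; spans myelinated arrivals over 6 cm |

All internal units are SI; μm/ms appear only at I/O boundaries. w_V is
interpreted as the Gaussian σ (the closed-form algebra is self-consistent
under this reading). Because σ_τ and V_p are amplitude-only factors,
absolute signal voltages are arbitrary up to one overall scale; all shape
and scaling analyses use ratios.

## Numerical choices

* **Convolutions** are discrete linear convolutions with zero padding; the
  Gaussian-AP second derivative is evaluated analytically on the target
  grid, tabulated waveforms by central finite differences (grid spacing
  ≤ w_V/20 recommended; the default Gaussian grids use w_V/50).
* **Closed-form Gaussian SFAP.** The convolution of two Gaussians carries a
  factor √(2π)·w_V w_g/w_C (w_g = w_φ/v); the closed form and the quoted
  peak magnitude √(2π)V_pΦ_pη w_φw_V/(v²w_C³) include it, so the closed form
  is identical to the numeric convolution rather than agreeing only up to a
  constant.
* **Lead-field interpolation** along the fiber is cubic inside the tabulated
  support and exactly zero outside, consistent with end-tapering.
* **End tapering** finds, from each end inward but only within that end's
  half of the profile, the first point whose local slope magnitude reaches
  `min_slope` (default: 1% of max|Φ| divided by the half-length), continues
  the tangent to its zero crossing, and zeroes beyond. If no point qualifies
  (e.g. a constant profile), the end is linearly ramped to zero over a 5%
  margin and a warning is logged.
* **Gauge invariance.** The recorded signal is independent of a constant
  lead-field offset exactly when membrane currents sum to zero over the
  profile window. On a finite window this holds for recording times at
  which the AP support lies fully inside the window; the invariance tests
  compare on that interior region. Tapered profiles remove the ambiguity
  altogether.
* **Point-source oracle.** Membrane currents are second *finite differences*
  of the travelling membrane potential, which telescopes to an exactly
  charge-conserving source set whenever the potential sits at baseline at
  the fiber ends (residual < 10⁻¹³ of the peak segment current in the
  shipped configuration).
* **Lobe counting** discards extrema below 5% of the global maximum
  magnitude and merges same-sign runs, suppressing numerical ripple.
* **Pattern search** operates on the parameter box normalized to [0,1]²,
  polling axis and diagonal directions; the mesh doubles (capped at 0.25)
  on success and halves on failure, stopping below a 10⁻⁶ normalized mesh
  or at the evaluation budget. The best-so-far history is monotone by
  construction. A Nelder–Mead fallback is provided. The forward model
  precomputes per-fascicle Φ(d,t) matrices and all fixed-population
  contributions, so one evaluation costs a matrix product plus one
  convolution (~5 ms at the shipped problem sizes).

## Synthetic nerve generator

`synth` emulates a minipig-scale vagus setup: an elliptical cross-section
(3 × 2 mm) holding ten non-overlapping circular fascicles (radii
120–250 μm, seeded rejection packing), an intrafascicular stimulating array
of two columns of eight contacts sharing the total current equally, and a
recording cuff of four 125 μm ring contacts with 3 mm spacing, 6 cm
downstream, each ring discretized into 16 point terminals. Per-fascicle
fiber counts scale with area (5·10⁹ myelinated and 2·10¹⁰ unmyelinated
fibers/m²) with an afferent fraction varying linearly across the section;
diameter densities are gamma (myelinated afferents k = 5, θ = 0.8 μm —
mean 4 μm; efferents k = 4, θ = 0.6 μm; unmyelinated k = 4, θ = 0.2 μm).
Recruitment thresholds follow a distance rule — the median total-current
threshold grows linearly with fascicle distance to the nearest stimulating
contact (15 μA base for myelinated populations at d₀ = 4 μm) — with a
log-normal within-fascicle spread of geometric SD 1.2. At the top of the
100–500 μA current sweep essentially all myelinated fibers are recruited;
at the 31.25 μA partial-activation scenario recruited fractions span
~0.1–0.8 across fascicles, which is what produces the correlation clusters
and large partial-recruitment deflections.

### What the generator does and does not emulate

Lead fields use the homogeneous-medium point-source kernel
1/(4πσ_e r) (σ_e = 0.3 S/m). Real nerves are strongly heterogeneous —
perineurium confines fields, endoneurium is anisotropic — so real lead
fields are more compact along the fiber than the 1/r surrogate. Two
consequences matter for interpreting passing tests:

* absolute eCAP amplitudes and inter-fascicle amplitude ratios are not
  predictive of tissue-resolved models;
* the long 1/r tails let slow unmyelinated populations contribute a small
  residual inside the 25 ms window even though their AP fronts (0.1–1 m/s)
  reach the cuff only near 60–600 ms. Population-level mechanism tests
  (per-fascicle plateau at full recruitment, cutoff-driven amplitude
  enhancement) are therefore demonstrated on myelinated populations, whose
  arrivals lie inside the window.

Passing tests show that the reciprocity machinery, the diameter scalings
and the recruitment mechanisms are implemented correctly, not that any
specific biological nerve is reproduced.

## Design choices

* Afferents and efferents share one AP waveform per myelination class;
  distinct fiber types exist so counts and recruitment can differ.
* All recruited fibers fire simultaneously from one initiation arclength
  (single-pulse stimulation, 50 Hz-class repetition effects excluded).
* Myelinated fibers are treated as continuous line sources; Ranvier-node
  discreteness is a known refinement that matters only when Φ varies on the
  internodal length scale.
* Recruitment curves are non-decreasing by construction; conduction block
  and non-monotone recruitment at high intensity are out of scope.
* The inverse fit targets the myelinated-afferent gamma parameters only,
  with efferents fixed and unmyelinated populations excluded from the
  shipped fit problem — a deliberately small proof-of-concept. The shipped
  fit problem uses a 3-fascicle myelinated nerve at the partial-activation
  current, a ±30% perturbed start, and a 500-evaluation budget; it recovers
  both parameters to ~10⁻⁶ relative error in ~400 evaluations.

## Known limitations

* No finite-element or layered-tissue lead fields; external solver output
  can be supplied through the profile file interface instead.
* No stimulus artifact, background activity, or pulse trains.
* The per-fascicle amplitude-versus-current maximum ("rise then fall")
  requires a steep recruitment curve; with the default log-normal threshold
  spread the fixture's per-fascicle curves are smoothed to monotone, and
  the effect is demonstrated with a sharp (single-threshold) titration.
* Fitting more than one population, or fitting measured (rather than
  self-generated) signals, is untested territory: the L1 landscape may
  become degenerate, as multiple parameter combinations can produce nearly
  identical signals.
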