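# Methods

## The viability statistic

The assay treats fluorescence, not cell counts, as the measurand. For
one channel the *sum intensity* is `S = Σ p` over all pixels with
`low ≤ p ≤ high`, grey levels 0–255, `high = 255` always. Field
viability is `100 · S_FDA / (S_FDA + S_PI)`; it is well defined exactly
when at least one channel carries above-threshold signal, and is
reported as NaN with an `undefined` flag otherwise (never silently 0 or

100). The statistic is scale-invariant — multiplying both sums by any
c > 0 leaves it unchanged — which is why calibration only needs to
equalise the *per-cell* response of the two channels rather than fix
absolute units.

Batch aggregation pools sum intensities across fields before applying
the formula (a signal-weighted estimate that matches "signal FDA over
total signal" and is robust to sparse fields); per-field percentages
are reported alongside for inspection, and per-bead percentages come
from applying the formula inside segmented bead regions. Pixels
selected by both channels' windows contribute to both sums; no
exclusivity rule is imposed.

## Synthetic bead fields

The generator emulates the production imaging conditions rather than
optics: its purpose is to give every pipeline stage a ground truth.

* **Bead population.** Diameters are normal with mean 525.8 µm and SD
  95 µm (the encapsulated-bead population at production; resampled
  below 50 µm). Beads are placed by rejection sampling without overlap,
  with an optional controlled *touching pair* (centre distance
  `r₀ + r₁ − f·min(r₀, r₁)`) for segmentation stress tests. At the
  default packing (~45 beads in a 1280² frame) sequential placement can
  jam, so the layout restarts from fresh draws of the same stream; the
  result remains a pure function of (params, seed).
* **Cell content.** Total cells = density × total bead volume,
  allocated per bead by largest remainder so the requested count is hit
  to ±1; the live/dead split uses the same allocator. Defaults: 22 × 10⁶
  cells per mL of beads, the harvest-relevant density (calibration
  deliberately includes 22 and 26 × 10⁶ samples).
* **Rendering.** Each cell is a Gaussian blob (σ = 15 µm ≈ one cell
  diameter) at a uniform position inside its bead, accumulated as a
  point mass and convolved once per channel with a normalised kernel.
  Because the kernel is normalised and beads keep a margin from the
  border, the total pre-clip signal is exactly
  `n_cells × per_cell_intensity × exposure/reference` — the linearity
  the assay relies on, testable to 1e-6. Live cells write only to the
  FDA channel, dead only to PI, with optional crosstalk fractions
  (default 0) and an optional low-density FDA dimming knob (default
  off; the validation data hint at reduced FDA signal at
  3.4 × 10⁶ cells/mL but give no mechanism).
* **Intensity anchoring.** `per_cell_intensity` (default 1200 grey·px)
  is the integrated per-cell signal at each channel's *reference
  exposure* — 150 ms FDA, 1000 ms PI, the exposures the original
  set-up settled on — so the signal-equivalence requirement holds by
  construction at those settings and calibration has a true optimum to
  find. The default brightness keeps fully live fields essentially
  unclipped at 150 ms while 200 ms and longer clip visibly, giving the
  SNR-based exposure selection a realistic landscape.
* **Background and noise.** Background = constant dark offset (default
  1 grey level) + a light-dependent term scaling with exposure (default
  2 at reference), plus Gaussian read noise (default SD 1) before
  quantisation and clipping at 255. The dark offset is what makes SNR
  genuinely increase with exposure below clipping; with it set to zero
  and no clipping, SNR is exposure-invariant and ties resolve to the
  shortest exposure.
* **Seeding.** One integer seed per field; geometry (diameters,
  centres, cell positions) and pixel noise use separate child streams,
  so geometry is stable when only the noise level changes. The
  pre-quantisation float image is kept on `ChannelImage.analog` for
  linearity checks; files on disk are 8-bit TIFFs.

What the generator does **not** model: PSF fidelity, photobleaching,
illumination gradients, spheroid substructure, autofluorescence
texture. Passing recovery tests therefore shows the *quantification
chain* is unbiased under controlled imaging, not that any real
microscope is calibrated; real deployments must calibrate on their own
control beads.

* **Lethal insult.** The Me₂SO kill is modelled as first-order decay of
  the live fraction, `exp(−rate · minutes)`, cells conserved. The rate
  (default 0.35 min⁻¹) is chosen so the 15-minute preset leaves <1%
  viability, consistent with its use as a 0%-viability control; the
  5/10/15-minute presets then give strictly decreasing viabilities like
  the graded validation samples.

## Calibration

* **Exposure selection.** SNR = (sum intensity over cell pixels) ÷
  (sum intensity over non-cell pixels), pooled over the fields at each
  candidate. Cell pixels come from ground-truth bead interiors on
  synthetic fields and from a provisional Otsu split on real images
  (the original description of "pixels representing cells" is visual,
  not algorithmic). Candidates with more than `max_saturated_fraction`
  (default 1%) of pixels at 255 are excluded; SNR ties within 1e-6
  relative resolve to the shorter exposure (less photodamage, less
  clipping risk).
* **Low threshold.** Per field: the robust background is the histogram
  mode + k·MAD (k = 3); the threshold is the minimum integer above it
  that still retains every connected cell region (raising it can only
  lose regions, so this is the first level above background provided
  all populated regions reach it — regions that never rise above
  background trigger a warning). The batch value is the mean of
  per-field integers, rounded half-up (a documented convention; whether
  the original per-image values were integers before averaging is
  unstated). Background-only fields are excluded, not averaged in.
* **PI matching.** With the FDA reference fixed (fitted threshold, mean
  sum intensity per live cell on live controls), the matcher scans
  (candidate exposure, threshold) pairs on killed controls and takes
  the pair minimising the relative per-cell mismatch, requiring it
  within a 5% tolerance (the original criterion is "no significant
  difference"; 5% is the package's numeric operationalisation).
  Thresholds are scanned only above the robust background, so a match
  can never be bought with background pixels. Failure reports the best
  achievable mismatch.
* **Overspill.** On single-channel-content controls, the wrong-channel
  above-threshold sum over the source-channel sum, pooled; pass when
  both directions are below 1%. In-bead background inflates the ratio
  slightly (a 10% injected crosstalk reads ≈ 0.11–0.12), which is
  acceptable for a screening check.

## Segmentation

Bead regions are found from the union of above-threshold pixels in both
channels: binary closing (disk 3), hole filling, removal of
sub-bead-sized debris, then a distance-transform watershed seeded by
distance maxima at least one minimum bead radius apart. The contract —
≥95% of beads recovered with centre error <10% of the radius, touching
beads split — is normative; the mechanism is replaceable. Each pixel
belongs to at most one bead.

## Bioreactor metrics

* **Oxygen consumption**: `(ΔDO/100 · sat_uM) · flow[L/s] / cells ·
  1e9` fmol/cell/s. The percent-to-concentration conversion is an
  explicit argument (default 200 µmol/L at 37 °C air saturation)
  because the original conversion is unstated; the published
  0.153 fmol/cell/s day-12 figure also folds in unquantified direct
  chamber oxygenation and is therefore documented as not independently
  recomputable from desk inputs. Negative drops are returned with a
  warning, not raised.
* **Rates** (bilirubin functional value, protein secretion) are OLS
  slopes over a configurable window, default from hour 1 onward to
  exclude the initial dilution of plasma into the hydrogel, times the
  compartment volume (mean over the window), unit-converted and
  normalised per 10¹¹ (bilirubin) or 10⁶ (secretion) cells.
* **Protein AUC** integrates the mass curve (concentration × volume)
  trapezoidally over time in hours, the "total mg produced" summary
  convention; it is additive over concatenated windows.
* **Nutrient bounds** are strict, as written for the process: glucose
  must stay *above* 15 mM and lactate *below* 10 mM, so boundary values
  violate.
* **Media regimes**: the shipped default schedule is days 4 (50%),
  7 (60%, representing the documented 50–60% change), 9 (70%),
  11 (80%). The earlier-variant day list (4/5, 7, 11) is provided as a
  named alternative with its documented 25% day-5 change; its later
  proportions are not recorded and follow the default escalation.
* **DO setpoint recipe**: escalates 21 → 35% when post-chamber DO falls
  below a configured trigger, never de-escalates, idempotent at the top
  setpoint. The trigger level is a required configuration value — no
  source default exists.

## Numerical and design choices

* Thresholding is inclusive on both bounds (`low ≤ p ≤ high`).
* Viability with zero total signal is NaN + flag, not an exception.
* The allocator (largest remainder) is deterministic with stable index
  tie-breaks; generation is bit-reproducible from (params, seed).
* Test and validation runs use scaled-down fields (typically 6–10 beads
  in 700² frames) as the package's standard desk-scale configuration;
  bead geometry, densities, exposures and noise keep production
  defaults, and nothing in the pipeline depends on frame size.
* Known limitations: single-plane by design (no z-stacks), no
  flat-field correction, no modelling of MTT/trypan alternatives, no
  closed-loop process simulation, and the synthetic-data caveats above.
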