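# Methods

This note documents the models, conventions and numerical choices behind
`pamp`, in the order data flows through the package.

## Synthetic phase movies (`pamp.simulate`)

The generator emulates a multi-position QPI time-lapse of adherent cells
on glass: by default 241 frames at 5-minute intervals (20 h, about one
cell cycle), 0.65 µm/pixel, illumination wavelength λ = 0.66 µm and
specific refraction increment α = 0.18 µm³/pg. Phase stacks are float32,
in radians, with cell-free background exactly 0 (plus optional Gaussian
read noise, default σ = 0.02 rad).

**Cell shape and mass.** Each cell is an anisotropic 2-D Gaussian
dry-mass profile truncated at 3σ, with axis ratio `elongation`
(default 2, an elongated migratory morphology whose continuous-ellipse
circularity is ≈ 84%) aligned to the instantaneous velocity. The
amplitude is normalised so the truncated integral equals the cell's
dry mass exactly; rasterisation at pixel centres then reproduces that
mass to ≪ 1% (midpoint quadrature of a smooth profile). Default masses
are 250 ± 50 pg over a 15 µm footprint radius, giving mean densities
around 0.35 pg/µm² — the scale seen in adherent tumor lines. The
optional exponential `mass_growth_rate_per_h` (default 0, so the
constant-mass invariants hold; 0.035/h ≈ one doubling per 20 h when
divisions are enabled) keeps population mass balanced through divisions.

**Motility.** Cell centres follow an Ornstein–Uhlenbeck velocity
process — the standard persistent-random-walk model of mesenchymal 2-D
migration — integrated *exactly* at frame times using the joint
position/velocity transition covariance, so there is no time-step error.
`speed_mean_um_h` is defined as the expected frame-to-frame step speed
at the configured sampling interval: for per-axis stationary velocity
s.d. `s` and persistence time τ, the sampled displacement has per-axis
variance 2s²τ(Δt − τ(1 − e^(−Δt/τ))) and the isotropic 2-D step length
is Rayleigh, so `s` is chosen to invert E[step]/Δt = target. This makes
recovered mean step speeds unbiased by construction rather than only in
the τ ≫ Δt limit. Defaults: 30 µm/h (fibrosarcoma-scale; tumor-line
controls in this assay class range ≈ 13–35 µm/h) and τ = 60 min.

**Boundaries, divisions, drug effects.** Cells reflect elastically at a
margin of one footprint radius, so tracks stay complete and footprints
uncropped; reflections slightly fold long ballistic paths, which is why
the ballistic-limit meandering test uses slow cells in a large field.
Divisions arrive as a per-cell Poisson process (`division_rate_per_h`,
default 0); a divider's axis ratio relaxes to 1 over the 3 frames before
the split (dividing cells round up), then two half-mass daughters start
at ±0.6 radii with fresh stationary velocities and their own lineage
entry. A drug is modelled as a multiplicative speed factor plus a
circularity shift in percentage points, implemented by solving the
continuous-ellipse circularity relation for the adjusted axis ratio.
Fields whose expected total footprint exceeds 80% are rejected as
overcrowded.

**Hologram forward model.** `simulate_hologram` produces the off-axis
interference pattern I = 1 + c·cos(2π f·x + φ) for a carrier f below
Nyquist and above a separation floor of 8 cycles per field.

What the generator deliberately does *not* emulate: optical aberrations
and coherence-gating sectioning, halo/shade-off artefacts, cell–cell
adhesion and contact inhibition, apoptosis, and 3-D environments. Tests
passing on these movies therefore validate the measurement chain
(segmentation → tracking → morphometry → dynamics → statistics), not
robustness to every imaging artefact of real recordings.

## Hologram reconstruction (`pamp.holography`)

Reconstruction is Fourier sideband demodulation, engineered to avoid
border leakage: the hologram is demodulated in real space by the carrier
(putting the object term exactly at baseband for any carrier direction),
reflection-padded as a complex field (reflection keeps baseband at
baseband and every interferer at radius ≥ |f|), apodised with a Tukey
window whose taper lies wholly in the padding, low-pass filtered with a
raised-cosine disc of radius |f|/2, and cropped. A four-pass fixed point
re-estimates the DC offset and conjugate sideband and subtracts them
before re-demodulating; each pass contracts the residual border leakage
by roughly its own magnitude, ending near 10⁻⁵ rad RMS on noise-free
fringes (the acceptance bound is 0.05 rad). Carriers must satisfy
|f| ∈ (0, 0.5) with the sideband disc clear of both the DC term and the
aliased conjugate at 1 − 2|f| (in practice |f| ≲ 0.38 cycles/pixel).
Phase is unwrapped with the 2-D unwrapper from scikit-image; a plane
fitted on a 4-pixel border ring (assumed specimen-free) is removed and
the border median set to 0 rad — note this absorbs any *global* linear
component of the object phase, which is indistinguishable from carrier
tilt. `detrend_background` fits a degree-2 polynomial over a user-given
cell-free mask (falling back to a global median shift, with a warning,
when background is under 10% of the field).

## Segmentation and tracking (`pamp.segmentation`, `pamp.tracking`)

Detection runs on the dry-mass density map with a two-level scheme:
cores from Otsu's threshold floored at 3× the robust background noise
s.d. (1.4826·MAD), support from a low threshold (the noise floor, or 2%
of the frame peak when noise-free), holes filled, and a watershed on the
smoothed density (σ = 2 px) seeded from local maxima at least 8 µm apart
splits touching cells. Regions under `min_area` (default 50 µm²) are
dropped. The low support level is what makes label mass track true cell
mass: a hard Otsu cut alone clips 20–40% of a Gaussian-profiled cell's
mass in the tails, while the two-level scheme loses ≈ 1–3%. Border-
touching labels are kept for counts but flagged, and flagged cells are
excluded from morphology statistics because their area and perimeter are
clipped.

Linking is optimal bipartite (Hungarian) matching on WCG distance
between consecutive frames, gated at `max_link_distance` (default 15 µm
≈ 5× a 35 µm/h step at 5-minute sampling) per frame of separation, with
gap closing up to 2 frames. Divisions are geometric: an unmatched
detection whose nearest already-matched neighbour sits within the gate
closes that parent and opens two daughters with recorded lineage.
Coordinates are 0-based pixel centres; physical position = index × pixel
size.

## Morphometry (`pamp.morphometrics`)

Formulas as in the README. Numerical conventions worth stating:

* **Perimeter.** Moore-neighbour boundary tracing with Jacob's stopping
  criterion gives the boundary-pixel chain; the reported length is the
  corner-cut (midpoint) polygon of that chain. The plain chain length
  (axial 1, diagonal √2) overestimates smooth convex contours by ≈ 5%
  (digitised disc circularity ≈ 91%); corner-cutting reduces the bias to
  ≈ 1% so digitised discs score ≥ 95% and usually clamp at 100%. A
  single pixel is assigned the minimal 4-step contour. Interior holes
  are ignored (outer boundary only).
* **Circularity clamping.** Values above 100% (possible for digitised
  discs with a slightly short perimeter estimate) clamp to 100 and are
  logged, keeping the classification bins total on (0, 100].
* **Negative densities** inside masks (noise pixels after background
  flattening) are kept, not clipped, so mass stays unbiased.

## Dynamics and classification (`pamp.dynamics`, `pamp.classify`)

Speeds are raw 5-minute step speeds — no smoothing — so tracking jitter
adds a small positive bias at low speeds; per-cell means over an
analysis window are the unit of population statistics (stated in the run
metadata). Analysis windows are half-open, (0, 10] and (10, 20] hours,
with a step assigned to the window containing its end time; a track
needs ≥ 12 steps (1 h) inside a window to enter population statistics.
Daughter tracks restart t₀ at their division frame, so displacement and
meandering are measured from birth. The meandering index returns 0 for a
zero-length path (stationary convention). Invasive-phenotype eligibility
at an evaluation time requires the track's observed span to cover that
time (within half a frame); thresholds (100 µm, 25%) are strict
inequalities. Density snapshots use the single frame nearest 0/10/20 h
(±15 min), matching snapshot-table semantics rather than period
averages; percent changes are computed from full precision, so they need
not match values recomputed from rounded table entries.

Control QC is advisory only: flags for end count < start count, for
|mean mass or area change| over the recording above 30%, and for a
period-2 vs period-1 mean-speed change above 50%.

## Statistics (`pamp.stats`)

The F-test is two-tailed: F = s²ₐ/s²_b on (nₐ−1, n_b−1) d.f., p =
2·min(P(F≤f), P(F≥f)) capped at 1. The gate reads "F-test p < 0.05 ⇒
Welch t-test, else pooled t-test" — the standard variance-gating
practice. No multiple-testing correction is applied by default (stars
are per comparison); this matches spreadsheet-style screening reports
and is recorded in the output metadata. The gated procedure's empirical
type-I error at n = 30 sits near 0.052 — the variance pre-test makes it
very slightly anti-conservative, which the acceptance band (0.04–0.06)
covers. Treated conditions are compared only against the control from
their own acquisition batch; cross-batch comparisons raise an error.

## Problem sizes used in tests and acceptance

Unit tests run on small fields (128–384 px, ≤ 60 frames). The parameter-
recovery benchmark uses 20 noise-free cells at 12.7 µm/h (a tumor-line
control speed scale at which a useful subset of cells stays isolated for
the full 20 h, so track-identity accuracy is well defined) on a 960²
field for 241 frames. The end-to-end discrimination study uses three
50-cell, 512², 241-frame movies (control, half-speed drug, null drug)
with divisions and mass growth enabled. These sizes keep a full
acceptance run to a few minutes on one CPU while leaving the per-group
sample sizes (≈ 50–200 per-cell period means) large enough for stable
inference.

## Known limitations

* Segmentation merges touching cells when their smoothed density peaks
  fall within the seed distance; merged intervals fragment tracks, which
  mildly depresses invasive-phenotype fractions at late evaluation times
  (daughters and re-started fragments measure displacement from their
  own first frame).
* The perimeter estimator is tuned for smooth convex-ish cells; deeply
  concave or filopodial outlines would need a finer boundary model.
* The hologram reconstructor assumes a specimen-free border ring for
  flattening and cannot distinguish a global linear object phase from
  carrier tilt.
* The OU motility model has no interaction between cells; crowding
  effects on real migration statistics are not represented.
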