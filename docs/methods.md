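# Methods

This note documents the models, numerical choices and known limitations of
`mesoswell`, in the order the pipeline applies them.

## Forward model (synthetic patterns)

A synthetic curve is a power-law background A·q⁻ᵖ + c plus one pseudo-Voigt
peak per allowed reflection, with Gaussian noise of standard deviation
noise_scale·√I added pointwise (Poisson-like counting statistics; a full
detector model would add gain, dark current and smearing, none of which the
downstream analysis is sensitive to at the level tested). Reflection
positions follow the lattice:

* lamellar: q_n = n·2π/d;
* hexagonal: q_i = r_i·4π/(√3·a), r_i ∈ {1, √3, 2, √7, 3};
* cubic: q_i = r_i·2π/a with r_i = √(h²+k²+l²) of the configured set.

Defaults: q grid 0.012–0.67 Å⁻¹ with 800 points (a typical laboratory SAXS
range), peak FWHM 0.004 Å⁻¹, pseudo-Voigt mixing 0.5 (no instrumental line
shape is assumed; the mixing parameter is configurable and nothing
downstream depends on it), background A = 1, p = 2, c = 5 in the arbitrary
intensity units of the generator (the q⁻² low-q rise is strong — about 7×
the first-order peak at the grid edge — deliberately stressing background
subtraction). The intensity fall-off per reflection order is not physically
modelled; relative amplitudes default to 1/i² decay and are free
parameters. Identical seeds give bitwise-identical curves.

Ground-truth peak centers and lattice parameters travel in the curve
metadata (and in a JSON sidecar when written to disk), so detection and
indexing can be scored exactly.

### Swelling laws

The ideal-dilution law treats the lamellar stack as one-dimensional
dilution: d = d_hc/φ_hc, with φ_hc the hydrocarbon volume fraction computed
from the water weight fraction assuming unit mass densities for lipid and
water (the same simplification implicit in decomposing d into thicknesses)
and an optional headgroup volume fraction of the lipid counted with the
aqueous slab. The bridging-capped law imposes d ≤ d_hc + d_w_max,
representing an adsorbed multivalent polymer that tethers adjacent bilayers
and stops swelling once the aqueous gap reaches the tether length. Defaults
d_hc = 27.1 Å (the hydrocarbon thickness of a fluid PC bilayer) and, for
the capped law, d_w_max = 67 Å in the tests — the regime where a
~19-residue disordered segment (contour length 72 Å) can still bridge.

## Background subtraction

A·q⁻ᵖ + c is fitted with counting-statistics weights (σ ∝ √I), iterating
up to five times and each round excluding points whose standardized
residual (I − model)/√model exceeds 3. Bragg peaks sit many σ above the
background and leave the fit support after the first round; the symmetric
noise of peak-free regions is retained, so the fit is unbiased across the
four intensity decades of the default grid. Bounds: A, c ≥ 0, 0 ≤ p ≤ 6.
If the optimizer fails the curve is returned unchanged with a warning flag;
subtracted curves may contain small negatives, which are kept in the data
(clipping would bias peak shapes) and flagged in the metadata.

## Peak detection

The curve is lightly smoothed (Savitzky–Golay, window 5, order 2;
disableable), maxima are found with a minimum separation of 0.005 Å⁻¹, and
a peak is kept if its prominence passes two gates:

1. relative: ≥ 2% of the largest prominence in the curve;
2. local significance: ≥ 5× the local noise scale, estimated as a rolling
   (31-sample) median absolute deviation of the smoothing residual.

The second gate exists because counting noise grows as √I: where the
power-law background is large (low q) the noise wander easily exceeds a
few percent of the strongest peak, and a purely relative threshold would
promote it to spurious reflections. Each retained center is refined by a
parabola through the three samples around the maximum (clamped to ±half a
grid step), which recovers sub-grid positions on noiseless data; refinement
can be switched off.

## Indexing and phase classification

**Lamellar.** Orders are assigned as nearest integers to q_i/q_first (gaps
such as a missing third order are allowed), a straight line q = slope·n +
intercept is fitted by least squares with a free intercept, and
d = 2π/slope. A fit is rejected when any matched peak misses its predicted
position by more than the relative tolerance (default 1%); a significant
intercept (|intercept| > 3× residual RMS) only raises a mis-indexing
warning, since forcing the line through the origin is also available but
not the default. The reported d_uncertainty is the sample standard
deviation (ddof = 1) of the per-reflection values d_n = 2πn/q_n — zero for
exact input — with the standard error available as a configuration choice.

**Ratio lattices.** For hexagonal and cubic sets, every (peak, ratio) pair
is tried as an anchor; peaks are greedily matched to their nearest ratio
within tolerance (each ratio used once, closest peak wins), the unit
spacing is re-estimated by least squares, and the matching is refreshed
once. Hexagonal needs ≥ 2 matched ratios, a cubic candidate ≥ 3. Shipped
cubic sets are √(2,3,4,6,8,9) (Pn3m-type), √(2,4,6,8,10) (Im3m-type) and
√(6,8,14,16) (Ia3d-type); the labels are conventional and cubic results
are always ranked candidates, never asserted space groups.

**Classification.** All lattice types are fitted and ranked by
(1) matched *significant* peaks — prominence ≥ 10% of the strongest — so a
lattice cannot win by sweeping up borderline noise bumps, (2) total
matches, (3) parsimony (lamellar < hexagonal < cubic), (4) residual. The
parsimony rule matters because the integer ratios 1, 2, 3 are a subset of
the hexagonal sequence: pure lamellar data fit both lattices equally well
and residual jitter must not flip the call. Residual-before-parsimony
orderings were tried and discarded: with noise they misclassify lamellar
patterns as hexagonal and let a 3-peak cubic fit outrank a 5-peak
hexagonal fit. If peaks remain unexplained and coexistence is allowed, a
second lattice is fitted greedily to the leftovers (two lattices at most —
more is not observed in the systems targeted); every peak ends up in
exactly one fit or in the unassigned list.

## Hydration analysis

Osmotic pressure uses Δμ_w = RT·ln(RH/100) and Π_osm = −Δμ_w/V_w with
R = 8.31446 J/(mol·K), V_w = 1.805×10⁻⁵ m³/mol and default T = 300.15 K
(27 °C). Π_osm is reported nonnegative, zero exactly at RH = 100. Note the
common compact way of writing this relation equates −Δμ_w/V_w with
(RT/V_w)·ln(RH/100), whose right-hand side is nonpositive; the two differ
by sign and this package consistently uses the nonnegative (pressure)
convention without speculating about any source's intent.

d_w = d − d_l contains both the polar headgroups and the interbilayer
water; d_l is assumed hydration-independent (a standard osmotic-stress
assumption, stated explicitly because it is only strictly verified at the
hydration extremes). d ≤ d_l warns rather than errors.

Swelling series are sorted by hydration (wt% water and %RH axes are tagged
and never mixed); the plateau is the first point after which every step
changes d by less than 2% (configurable), requiring at least two plateau
points, and plateau_d is the mean over the plateau. Phase maps place
interval boundaries midway between adjacent measurements with a
"not determined" flag — the true boundary is only bracketed.

## Bridging model

Extended length is n·3.8 Å (Cα–Cα virtual bond). The coil span is linear,
n·3.26 Å, an *effective* per-residue value back-derived so that 8- and
19-residue segments give 26 and 62 Å; it is labelled as such because a
proper excluded-volume coil scales as b·nᵛ (the Flory option, defaults
b = 5.5 Å, ν = 0.57, provided for sensitivity analysis — note a linear
26–62 Å range cannot come from ν < 1 scaling, hence the effective-linear
default). Verdicts per segment: coil_possible (coil ≥ d_w),
extended_only, excluded (contour < d_w); they are monotone in d_w. Every
report carries the caveat that d_w includes the headgroup region, so d_w
slightly above a segment length does not exclude bridging. The packaged
6-K-segment architecture uses synthetic representative segment lengths
(8, 11, 14, 17, 19 aa) and a +50 bound-state charge inferred from
electroneutrality (0.1 mol% protein neutralising 5 mol% monovalent anionic
lipid); both are overridable, and sequence-exact values should be used
when known. Anionic lipids are treated as monovalent (PG/PS).

## PT ssNMR ratios

Ratios r_CP = I_CP/I_DP and r_INEPT = I_INEPT/I_DP are computed per carbon
from peak-intensity tables (DP involves no polarization transfer and is
the natural reference). Regimes: mobile (r_INEPT ≥ 0.3 and > r_CP), rigid
(r_CP ≥ 0.3, r_INEPT below the 0.05 detection floor), undetected (all
intensities below the floor relative to the strongest DP signal),
intermediate otherwise. Between samples, a carbon is flagged when its
r_INEPT drops by more than 20% relative. All thresholds are configurable
defaults: polarization-transfer intensities depend on both the rate and
the anisotropy of C–H reorientation and are not quantitative order
parameters, so the regimes and flags are qualitative screening aids, and
no printed reference intensities exist to calibrate them against. Crowded
spectral regions may be entered as one pooled label (e.g. "C4-C13").

## Pipeline

The batch runner executes read → background → peaks → classify →
decompose → series/phase-map per manifest row, failing rows individually
and erroring only if every row fails. Reports carry the configuration (and
its SHA-256 hash), package version and per-curve seeds; identical inputs
and configuration give byte-identical CSV outputs. Configuration is one
YAML file whose keys mirror the module defaults listed above.

## What the synthetic tests do and do not show

The generator reproduces the features the analysis depends on — reflection
positions, relative intensities, a strong low-q background, counting
noise, phase mixtures, swelling laws — with exact ground truth. It does
not emulate instrumental smearing, mosaic or texture effects, form-factor
modulation of reflection intensities, beamstop artifacts, or chemical
degradation across a hydration series. Passing round-trip tests therefore
demonstrates the correctness and noise robustness of the *analysis*, not
detector-level fidelity; on real data the peak-shape and background
parameters may need adjustment, and weak high-order reflections near the
detection limit remain the dominant failure mode (test conditions: 800-
point curves, 25–50 replicates per statistical check, peak SNR 20 — sizes
chosen to make the statistics stable while keeping the full suite in a
few seconds).

## Known limitations

* Cubic indexing ranks candidate ratio sets only; intensity-based
  symmetry arguments and electron-density reconstruction are out of scope.
* The order-assignment step assumes the first matched peak is a low order
  of the lattice; pathological patterns whose first order is entirely
  absent from the measured q range will be mis-indexed (flagged via the
  intercept warning where detectable).
* Coexistence handling is limited to two lattices.
* d(RH) is not predicted from interaction potentials; the package measures
  and summarises, it does not model forces.
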