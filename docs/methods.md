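# Methods

## Binding models and fitting

All concentrations are nM; protein concentrations refer to the assembled
binding unit (the tetramer) unless a caller states otherwise.

**Direct titrations** are fit to the hyperbola
B = B_max·P/(K_d + P) + C, valid when the probe concentration is well
below K_d so the free and total protein concentrations coincide.

**Competition titrations** are fit to the hyperbolic decay
B = B_ini − C·D_c/(IC₅₀ + D_c). The amplitude C is a *positive,
subtracted* quantity: anisotropy falls as the competitor strips protein
off the labelled probe. IC₅₀ is phenomenological: for competitors much
weaker than the probe it is proportional to the competitor K_d, while for
strong competitors it is floored by the probe's own affinity. Both regimes
are demonstrated against the package's exact competition-equilibrium
solver (`solve_competition_equilibrium`), which solves the one-receptor /
two-ligand mass-action system by monotone bracketing (Brent, relative
tolerance 1e-15; mass balance conserved to 1e-9). IC₅₀ units follow the
dataset declaration (per-molecule, or per-nucleotide for heterogeneous
long-DNA competitors); the fitter is agnostic.

**Tight-binding titrations** (probe ≳ K_d) use the Morrison ligand-
depletion quadratic with effective site concentration S = n·[DNA]:
B = B_ini + B_max·[(P+S+K_d) − √((P+S+K_d)² − 4PS)]/(2S). This is the
unique quadratic consistent with the limits required of it: it saturates
at B_ini + B_max, gives a stoichiometric straight-line titration with
midpoint at P = S/2 as K_d → 0, and reduces uniformly to the hyperbola as
[DNA] → 0 (verified to <1e-3·B_max at S = K_d/1000). The stoichiometry
fit holds K_d at an independently measured value, shares one n across all
datasets, and gives each dataset its own amplitude and offset; 1/n (DNA
per binding unit) is reported as a derived quantity. Designs that cannot
identify n (a single dataset, or identical probe concentrations) are
flagged rather than silently reported.

**Fitting engine.** Unweighted trust-region least squares
(`scipy.optimize.least_squares`, tolerances 1e-14) with positivity bounds
on K_d, IC₅₀ and n, multi-start (5 seeded log-normal perturbations around
a data-driven initial guess) to avoid local minima. Asymptotic standard
errors come from the Jacobian at the optimum. On noiseless
model-generated data all fitters recover the generating parameters to
relative error < 1e-6 (property-tested over random parameter draws).
A fitted competition amplitude indistinguishable from zero leaves IC₅₀
undefined and flags the result instead of returning a number.

**Normalisation.** Percent-of-maximum-change, 100·(A − A_min)/(A_max −
A_min). Two conventions are provided because plateau estimation is
genuinely ambiguous: `observed` (sample extremes) and `fitted` (plateaus
from a model fit, robust to endpoint noise). K_d, IC₅₀ and n are invariant
under any affine transform of the signal, so the choice affects only the
reported amplitudes.

## Synthetic data

The generator's defaults are the study conditions the analysis modules
are validated under, not tuning knobs.

**DNA.** Discrete 2-D worm-like chains: equal steps of ~1 nm summing to
exactly n_bp·0.34 nm, per-step Gaussian turning angle of variance
step/P with persistence length P = 50 nm — the textbook value for
surface-equilibrated B-DNA; deposition itself is not modelled. The
ensemble mean-squared end-to-end distance matches the planar closed form
⟨R²⟩ = 2[λL − λ²(1 − e^(−L/λ))], λ = 2P. Bridged k-mers concatenate k
monomer chains (end-to-end by default; end-to-centre and centre-to-centre
junctions produce branched objects that the tracer excludes, mirroring
their exclusion from manual length censuses). Circles are closed polygons
with chord-corrected radius so the perimeter equals the contour exactly.
Chains that approach themselves closer than ~6 nm are resampled by
default (`avoid_self_crossing`), since crossed molecules cannot be traced;
molecule placement enforces a 10 nm clearance between neighbours, packing
~8 monomer-equivalents per 1000 × 1000 nm² field and spilling into
additional fields as needed.

**Topographs.** 1000 × 1000 nm² at 512 × 512 px by default. DNA is drawn
as a ridge of Gaussian cross-section (peak 0.5 nm, σ 2 nm) by max-blended
stamping at 0.3 px spacing; particles are sum-of-lobe templates (lobes:
2 nm tall, σ 4 nm; connecting rods 0.5 nm tall) with numerically
integrated ground-truth volumes. Tip convolution is grayscale dilation
with a spherical-cap structuring element (default radius 5 nm); dilation
can only widen and never raise features, and a 0.5 nm-tall smooth ridge
broadens only marginally — the effect is strong for tall, sharp features.
Per-scanline offsets and per-pixel Gaussian noise (default 0.05 nm RMS)
are added last. Heights are written as 32-bit float TIFF with a JSON
sidecar carrying the nm/px scale and generator provenance.

What the generator does **not** emulate: molecule–molecule crossings and
overlaps, surface-charge adsorption artefacts, thermal drift, probe
asymmetry, and the operator variance of manual profiling. Passing tests
therefore demonstrate correctness of the estimators under clean,
well-separated deposition, not robustness to every real-world artefact —
in particular the synthetic traced-length spread (~2–3 nm SD) is far
tighter than the ~22 nm SD typical of manual tracing of real images.

## AFM quantification

**Flattening.** Foreground is masked at median + 2 robust SD
(1.4826·MAD); each scanline has a polynomial background (order 0–2, fit
on background pixels only) subtracted, followed by a global plane and a
final median shift, leaving the background median at ~0.

**Tracing.** Threshold (default 0.25 nm, half the ridge height) →
8-connected components → topological skeleton → spur pruning (< 8 nm
branches ending at junctions) → path extraction on the skeleton graph,
with spurious diagonal links dropped when a 4-connected path already
exists. Lengths sum 1 px lateral / √2 px diagonal steps times the scale.
The raw chain code overestimates lengths at intermediate orientations by
up to ~8% (~5% on a 50 nm-persistence ensemble); the optional
`smooth_window=5` moving-average smoothing of the path removes most of
this staircase bias (circles then trace within 0.2% of their true
perimeter) but is off by default to keep the estimator assumption-free.
Closed skeletons are reported as circles; components touching the border
or retaining >2 endpoints after pruning (branched/crossing molecules) are
excluded with a reason and counted separately.

**Length statistics.** Histograms (Freedman–Diaconis bins) are fit with a
single Gaussian; the fitted mean tracks the dominant mode and is robust
to minority multimer populations. Degenerate samples return the common
value un-fit. Cumulative frequency is the right-continuous survival
fraction of molecules at least a given length.

**Bridging census.** Threshold = control mean + 1 SD (molecules longer
than this are candidate bridges); exact k-mers are lengths within
k·μ ± 2σ of the control fit for k = 2…5. The control σ is used for every
window (an alternative SD can be passed), windows are mutually exclusive
(requiring σ < μ/4, enforced with an explicit error), and sub-monomer
fragments are counted in the denominator but never as multimers. With
multimer traced lengths spreading roughly as σ·√k, fixed ±2σ windows
undercount higher multimers slightly; planted dimer/trimer fractions are
still recovered within ±2 percentage points at 500 molecules in the
end-to-end test.

**Particles.** Components above a low footprint threshold (0.3 nm —
below the connecting-rod height, or multi-lobed particles fragment);
spots are local maxima ≥ 1 nm tall, ≥ 10 nm apart, and prominent by
≥ 0.3 nm over the saddle to any higher spot (checked along the line
profile). Classes: I one spot, II one spot plus a tail (a skeleton
endpoint ≥ 10 nm from every spot), III two spots, IV three, V four or
more; a tail is ignored once two spots are present. The spot/tail
defaults were chosen on synthetic fixtures and are exposed as parameters.
Volumes integrate heights over the component bounding box padded by 8 nm
plus twice the tip radius, minus the median basal volume of up to five
equal-size blank windows — windows whose 10 nm-grown extent contains no
pixel above threshold, keeping neighbouring tails out of the basal
estimate. Negative estimates clamp to zero with a warning. The DNA
fiducial uses the same estimator over a fixed 20 × 20 nm² window centred
on a ridge (off-ridge windows are an error); note the window integrates
whatever ridge length crosses it, so curved or diagonal fiducial
placements read slightly high — placements on straight segments match
the analytic cross-section integral within 5%. Relative volume =
particle/fiducial; because both share the same tip, broadening largely
cancels and rendered volume ratios track ground truth within 10% for tip
radii ≤ 2 nm. Mass uses a linear calibration (default 380/4.4 ≈ 86.4 kDa
per relative-volume unit, user-overridable since the underlying
calibration line comes from reference data); without a calibration the
mass field is omitted, never defaulted.

## Sequence utilities

`protein_mass_and_extinction` sums average residue masses minus one water
per peptide bond (via Biopython) and applies the 280 nm additivity rule
(5500 M⁻¹cm⁻¹ per Trp, 1490 per Tyr, +125 per cystine when oxidised;
reduced cysteines assumed by default). Sequences come from FASTA files;
`load_uniprot_sequence` reads a locally cached accession and never
touches the network.

## Numerical and design choices

* Every stochastic routine takes an explicit integer seed (default 0);
  fixed seed ⇒ byte-identical outputs, including CSV/TSV/JSON files.
* Degenerate inputs raise informative errors rather than returning NaN:
  zero anisotropy denominators, equal normalisation extremes,
  unidentifiable fit designs, missing blank windows, off-ridge fiducials,
  overlapping multimer windows.
* The tight-binding discriminant is clamped at zero with a warning if
  rounding drives it negative.
* Thinning is not exactly 90°-equivariant at molecule ends; traced
  lengths of the same rod before and after image rotation agree within
  the 1 px-per-endpoint budget rather than exactly.
* Problem sizes in the test-suite and acceptance runs (250-molecule
  control ensembles, 500-molecule bridging mixtures, 500-replicate
  Monte-Carlo stoichiometry fits, 10⁴-chain polymer statistics) were
  chosen to give comfortable statistical margins for the assertions they
  feed.

## Known limitations

* The tracer does not disentangle crossing or overlapping molecules;
  they are excluded, which in crowded real images would bias a census.
* No multi-Gaussian deconvolution of length histograms — multimers are
  classified by windows.
* Tip convolution is purely geometric (dilation); no elastic tip–sample
  mechanics.
* The volume→mass map is linear by construction and only as good as the
  supplied calibration slope.
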