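# afmbind

Quantitative analysis of protein–DNA binding and bridging, combining two
experimental readouts in one tested package:

* **Fluorescence anisotropy titrations** — equilibrium binding isotherms
  for a protein binding a labelled DNA probe: the simple hyperbola, the
  competition (unbinding) decay yielding an IC₅₀, and the tight-binding
  (Morrison) quadratic with an explicit stoichiometry *n* fitted globally
  across probe concentrations. An exact mechanistic competition-equilibrium
  solver is included as an independent oracle for what an IC₅₀ can report.
* **AFM topograph quantification** — flattening, DNA backbone tracing and
  contour-length measurement, Gaussian fitting of length histograms,
  classification of contour-length multimers (the signature of
  intermolecular DNA bridging), and protein-particle morphology/volume
  analysis with fiducial-DNA normalisation and a linear volume→mass
  calibration.

Because raw instrument data for such studies are rarely deposited, the
package ships a first-class synthetic-data generator: noisy titrations
drawn from the binding models, and ground-truthed height maps of
worm-like-chain DNA, bridged multimers, circles and multi-lobed protein
particles, with tip convolution, scan-line offsets and pixel noise.

## Models

Anisotropy from polarised emission intensities:

    r = (I_VV − I_VH) / (I_VV + 2 I_VH)

Direct titration (non-depleting regime), protein concentration *P* (nM):

    B(P) = B_max · P / (K_d + P) + C

Competition unbinding, competitor concentration *D_c*:

    B(D_c) = B_ini − C · D_c / (IC₅₀ + D_c)

Tight binding with ligand depletion, effective site concentration
S = n·[DNA] (n = binding units per DNA molecule; 1/n = DNA per unit):

    B(P) = B_ini + B_max · [(P + S + K_d) − √((P + S + K_d)² − 4 P S)] / (2 S)

In the global stoichiometry fit, K_d is held at an independently measured
value, each probe-concentration dataset keeps its own amplitude and
offset, and a single *n* is shared.

The mechanistic competition oracle solves, for free receptor *R*,

    R · [1 + D_p/(K_p + R) + D_c/(K_c + R)] = R_tot

by monotone bracketing, from which probe occupancy — and hence the IC₅₀
that a phenomenological fit would report — emerges from mass action.

DNA contour lengths use 0.34 nm/bp (B-form); a 587 bp substrate is
expected at 199.6 ≈ 200 nm.

## Worked example

Simulate a noisy direct titration (true K_d = 16 nM, B_max = 100, 3%
noise) and fit it:

```
afmbind simulate-binding --model hyperbolic \
    --params '{"b_max": 100.0, "k_d": 16.0, "c": 0.0}' \
    --conc-grid '[0, 2, 5, 10, 20, 40, 80, 120, 160, 200, 250]' \
    --noise-sd 3.0 --seed 1 --out titration.csv
afmbind fit-binding --mode direct --in titration.csv --out fit.json
```

`fit.json`:

```json
{
  "b_max": 99.59703374231974,
  "c": 1.5246331516481166,
  "converged": true,
  "k_d": 16.84742751081737,
  "n_points": 11,
  "rss": 34.08781899550036,
  "stderr": {
    "b_max": 1.851961637612301,
    "c": 1.6554969707758072,
    "k_d": 1.400088246960907
  }
}
```

The fitted K_d of 16.8 ± 1.4 nM recovers the generating value within one
standard error; `rss` is the residual sum of squares over the 11 points.

The AFM side works the same way from the shell:

```
afmbind simulate-afm --preset fig6 --seed 0 --outdir afm/
afmbind trace --in afm/field_000.tif --out molecules.tsv
afmbind bridge-report --in molecules.tsv --control molecules.tsv --out bridge.json
```

or from Python:

```python
from afmbind import synthetic, afm_trace

chains, gt = synthetic.build_bridged_scene(250, seed=0)
fields = synthetic.render_scene(chains, gt, tip_radius_nm=5.0, noise_rms_nm=0.05, seed=0)
lengths = [m.contour_nm
           for topo in fields
           for m in afm_trace.trace_dna(afm_trace.flatten(topo))
           if m.valid and not m.is_closed]
dist = afm_trace.fit_length_histogram(lengths)
print(dist.mu)   # ~209 nm for the 587 bp substrate (199.6 nm true contour)
```

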