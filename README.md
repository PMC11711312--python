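# folliclemap

Morphometric and statistical analysis of vibrissa (whisker) follicle afferent
innervation from dense 3D axon reconstructions.

## The scientific problem

The follicle sinus complex of a rat whisker is innervated by a few hundred
mechanosensory afferents: myelinated Merkel, lanceolate, club-like and
Ruffini-like endings supplied by the deep vibrissal nerve, plus unmyelinated
fibers and a small superficial circumferential population. Dense
reconstructions of these axons (one SWC skeleton per axon, coordinates in µm,
with a sidecar table of annotations such as myelination, Ranvier node
positions and nerve-entry coordinates) raise a set of quantitative questions
this package answers:

- **Typing and census.** Afferent types follow a deterministic rule table on
  vertical ending territory (ring-sinus / ringwulst / cavernous-sinus level,
  relative to the ringwulst landmark) and ending flags (root-sheath entrance,
  glassy-membrane terminal, shaft-ward trajectory). What are the innervation
  proportions?
- **Angular polarization.** Terminal angular positions θ ∈ [0°, 360°)
  (0° = rostral, 90° = dorsal) are tested for a dorso-caudal bias with an
  exact two-sided binomial test on opposing semicircles, the cut rotating in
  20° steps.
- **Conduction-velocity gradient.** Estimated velocity (v = 6·d m/s for
  myelinated fibers of diameter d µm; v = 0.32·ln d + 2.8 m/s for
  unmyelinated) is regressed on terminal height, with a bimodal diameter
  split at 850 µm above the nerve entrance.
- **Axon arms and crossing.** Per-axon crossing index
  I = (N_intra − N_inter)/N_total from angular order changes between a
  reference level and the terminals, tallied within and across axon arms.
- **Unsupervised subtypes.** Gower dissimilarity on mixed continuous/binary
  afferent features, factor analysis of mixed data (FAMD) for visualization,
  Ward hierarchical clustering, and a two-sample comparison of the two
  club-like sub-clusters (fiber area, Ranvier internode length).
- **Nerve linearization.** Does the radial arrangement of afferents around
  the shaft map into the nerve cross-section as a condensed radial layout or
  as a linearly unwrapped band? Both models are scored by Pearson r between
  the model coordinate and the terminal angle unwrapped at a stated cut.

Because the analyses are defined independently of any particular dataset, the
package ships a ground-truthed synthetic follicle generator
(`folliclemap.synthetic`) that reproduces the statistical structure the
analyses assume — type territories and flags, von Mises angular bias, caliber
gradient, planted club-like subtypes, angular arm sectors, and all three
nerve layouts — so every stage is testable end to end.

## Worked example

```python
from folliclemap import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=7, out_dir="demo_run"))
print("composition:", summary["composition_percent"])
print("type shares:", summary["myelinated_type_percent"])
print("gradient velocity r:", round(summary["gradient"]["velocity_r"], 3))
print("crossing index mean:", round(summary["crossing_index_mean"], 3))
print("linearization:", summary["linearization"])
```

prints (abridged):

```
composition: {'superficial': 6, 'unmyelinated': 26, 'myelinated': 67}
type shares: {'ClubLike': 35, 'Merkel': 34, 'RuffiniLike': 17, 'Lanceolate': 14}
gradient velocity r: 0.809
crossing index mean: 0.335
linearization: {'linear_r': 1.0, ..., 'radial_r': 0.0549, 'radial_p': 0.506}
```

Reading the output: the simulated follicle (221 afferents at the default
study conditions) is 67% myelinated deep innervation, and the classified
myelinated population splits 34/14/35/17% into Merkel, lanceolate, club-like
and Ruffini-like types. Conduction velocity rises with terminal height
(r ≈ 0.81); the mean crossing index is positive (axons exchange angular order
mostly within their own arm); and because this follicle was generated with a
linearly unwrapped nerve layout, the linear model predicts terminal angles
almost perfectly (r ≈ 1.0) while the radial model does not (r ≈ 0.05). All
intermediate tables (features, exclusion log, polarization scan, cluster
labels, club-subtype comparison, ...) are written to `demo_run/`.

The same stages are available from the shell:

```bash
folliclemap simulate --seed 1 --out sim/
folliclemap classify --features sim/features.csv --out typed.csv
folliclemap gradient --features sim/features.csv
folliclemap linearize --features sim/features.csv --cut 0
folliclemap run --config run.yaml
```

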