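# helixsynergy

Tools for analyzing how the *distance* and *helical phase* of
transcription-activator binding sites control synergistic transcription
activation at engineered promoters.

Two activators bound to straight B-DNA sit at a relative azimuth fixed by
their center-to-center distance: with a twist of 36°/bp (10.0 bp/turn), a
site pair 25 bp apart projects to opposite sides of the helix, while 20 bp
puts both factors on the same side. For activator pairs such as GAL4-VP16
dimers or ZEBRA on ZIIIB elements, reporter activation across a spacer
series oscillates with exactly this geometry — maximal when the factors
straddle the helix — and the protein-DNA complex's gel mobility oscillates
in counterpoint, because an opposite-face complex projects wider
perpendicular to the DNA axis. This package implements that entire analysis
chain for both real tabular data and synthetic data:

- **helix_geometry** — idealized B-DNA phase geometry: azimuths, folded
  pairwise phases φ ∈ [0°, 180°], same/opposite-face classification
  (boundary 90°), even-spacing detection, axis-model construction.
- **structure_model** — PDB I/O (via biotite), ordered atom selection,
  least-squares (Kabsch) rigid superposition with RMSD, complex assembly,
  and the transverse-extent proxy for complex width.
- **emsa_analysis** — free-probe marker-line fit log(m) = a + b·L,
  detrending of saturated-complex mobilities, and tie-rule local-minimum
  detection (a run of near-equal lanes reports its middle lane).
- **activity_analysis** — firefly/Renilla normalization, peak detection
  (shared tie rule), a damped periodic fit
  A(s) = e^(−λs)·[b + a·sin²(π(s+c)/P)] estimating the helical repeat P,
  synergy ratios, template comparisons, titration dominance checks.
- **simulator** — an equilibrium occupancy model of the steric-hindrance
  ("concentration field") picture: per-state weights
  ∏ᵢK·∏ᵢⱼ exp(−w·g(φᵢⱼ)·e^(−dᵢⱼ/ξ)) with angular kernel
  g(φ) = cos^(2k)(φ/2), recruitment with same-face interference, and a
  Hill reporter response. This is the generative core for all synthetic
  data.
- **synthetic** — seeded generators for replicate luciferase tables, gel
  tables, toy PDB fixtures and template FASTA.
- **templates / cli** — the engineered promoter catalog (two-site spacer
  series; the 21 vs 27 bp center-to-center designs at 22/26 bp TATA
  offsets; three- and four-site arrangements; ZEBRA pairs) and a thin
  `helixsynergy` command-line interface over all of it.

## Worked example

```sh
python examples/spacer_series_simulation.py
```

```
noise-free model curve:
  peaks at spacers: [8.0, 18.0, 28.0, 38.0] bp
  min two-site/one-site ratio: 2.03 (synergy: True)
noisy triplicates (cv 10%, seed 1):
  detected peaks: [8.0, 18.0, 28.0, 38.0] bp
  fitted modulation period: 9.97 bp (helical repeat estimate)
```

With 17-bp GAL4 sites, spacers of 8, 18, 28 and 38 bp put the two dimers
25, 35, 45 and 55 bp center-to-center — folded phase exactly 180°, i.e.
opposite helix faces — and those are precisely the detected activation
peaks. The minimum two-site/one-site ratio above 2 means the pair is
super-additive (synergistic) at *every* spacing, and the fitted modulation
period recovers the ~10 bp/turn helical repeat from activity data alone.
The other scripts in `examples/` walk through face classification, gel
detrending (mobility minima at the same spacers), the ZEBRA series (a
single peak at 8 bp), and structural superposition with the
transverse-extent width proxy.

A matching shell workflow:

```sh
helixsynergy fixtures --outdir demo --seed 1
helixsynergy analyze-activity demo/activity.tsv --outdir demo --single-site-template G1
helixsynergy analyze-gel demo/gel.tsv --outdir demo
helixsynergy --show-defaults
```

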