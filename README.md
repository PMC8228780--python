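# occluwear

Quantifying occlusal tooth wear — the irreversible loss of tooth substance
on the biting surfaces — from serial 3D surface scans is a superimposition
problem: two digital models of the same crown, taken before (T0) and after
(T1) a period of wear, must be brought into a common frame using only
surface regions that did not change, and the lost volume then read off.
The hard case is the clinically common one in which the buccal and lingual
(cheek- and tongue-facing) surfaces have *also* changed a little — through
early caries, fillings, polishing, or scanner artefacts — so no crown
surface is perfectly pristine.

`occluwear` implements the full measurement pipeline for that scenario,
plus the in-silico apparatus to validate it without any physical scans:

* **Trimmed point-to-plane ICP** crown superimposition with the settings a
  dental measurement package exposes: *estimated overlap of meshes* (the
  fraction of distance-sorted correspondences kept per iteration),
  *exclude overhangs* (rejection of correspondences landing on the target
  mesh's open boundary), exact nearest-neighbour search, and repeated
  application until the fit stops improving.
* **Simultaneous crown slicing and identical flat hole-filling**: both
  crowns are cut by the same gingival (and, when needed, mesial/distal)
  planes; cut boundaries are split at sharp corners so every hole lies in
  a single plane and is closed by a deterministic flat fill. The wear
  volume is the difference of the two watertight volumes,

  ΔV = V(T0 part) − V(T1 part)  [mm³],

  each volume computed by the divergence theorem over the closed mesh.
* **A synthetic tooth generator** producing watertight premolar/molar-like
  crowns with seeded anatomical relief, to which occlusal grinding
  (≈0.5 / 1 / 2 mm vertical loss) and shallow buccal/lingual wear patches
  (3–5 mm extent, 100–250 µm deep) are applied with the true removed
  volumes known by construction — a gold standard (GS) that replaces
  superimposition on intact adjacent structures.
* **The six-technique comparison study**: GS plus partial-crown (PC) and
  complete-crown (CC) reference areas at 100 % (A), 80 % (B),
  user-defined (C) and 30 % (D) estimated overlap, compared with
  Friedman / Wilcoxon signed-rank / Mann–Whitney / Kruskal–Wallis
  statistics and Bland–Altman repeatability analysis.

## Worked example

Simulate two worn teeth, register one pair with the complete-crown 30 %
technique (CCD), and measure its wear volume:

```bash
occluwear simulate --n-teeth 2 --seed 7 --mesh-resolution 2000 --out data/
occluwear register --t0 data/tooth_00/t0.stl --t1 data/tooth_00/t1.stl \
    --technique CCD --init init.json --out reg.json
occluwear measure --t0 data/tooth_00/t0.stl --t1 data/tooth_00/t1.stl \
    --alignment reg.json --out wear.json --export-parts parts/
```

The register step prints the converged fit quality and the measure step
the volume difference of the sliced, flat-filled crown parts:

```
trimmed RMS 4.383e-08 mm (303 correspondences)
occlusal wear volume: 0.6929 mm^3
```

For this seed the generator's manifest (`data/truth.json`) records a true
occlusal wear volume of 0.6929 mm³ — the technique recovers the
construction truth to a few 10⁻⁵ mm³ at this coarse mesh resolution.
(`init.json` holds a 4×4 starting pose; in practice this is the operator's
rough manual pre-alignment, and `occluwear evaluate` draws it
automatically.)

Run the whole study replica and statistics battery:

```bash
occluwear simulate --n-teeth 36 --seed 1 --out data36/
occluwear evaluate --data data36/ --out report/
```

`report/` then contains `results.csv` (one row per tooth × technique),
`stats.json` (Friedman, pairwise Wilcoxon with Bonferroni adjustment,
subgroup tests, Bland–Altman repeatability), box-plot and Bland–Altman
figures, and a markdown summary.

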