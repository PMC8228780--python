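# Methods

## The measurement model

A wear measurement takes two triangle meshes of the same tooth crown in
millimetres — T0 before wear, T1 after — and produces the occlusal volume
loss in mm³. Three stages:

1. **Superimposition.** A reference vertex set on T0 (the whole clinical
   crown, CC, or two lateral buccal/lingual patches, PC) is registered
   onto the T1 surface by trimmed point-to-plane ICP. Each iteration
   finds the exact nearest surface point for every reference point,
   optionally discards correspondences whose nearest point lies on the
   target's open boundary ("exclude overhangs"), sorts the remainder by
   distance and keeps only the *estimated overlap* fraction, then solves
   the linearised point-to-plane least squares (6×6 normal equations,
   Rodrigues re-projection; closed-form point-to-point fit as a fallback
   for singular systems). The converged loop is re-run from its own
   result up to five times, stopping when a round improves the trimmed
   RMS by less than the convergence tolerance — the software-button
   analogue of an operator pressing "register" until the distance stops
   shrinking. Trimming is what makes low overlap settings robust: points
   sitting on changed (worn) surface acquire large distances and fall out
   of the kept set, so they cannot bias the fit.
2. **Slicing and identical filling.** A gingival plane, oriented along
   the crown axis (recovered in any pose from the largest exactly planar
   face cluster, the flat gingival base of the synthetic crowns), is
   placed by taking the operator's stated objective literally: scan
   candidate cut heights and minimise the number of changed
   laterally-facing vertices kept above the cut plus changed
   occlusally-facing vertices lost below it, where "changed" means
   |signed distance| > 50 µm between the aligned pair. Both crowns are
   cut by the same plane(s); cut boundaries are chained into loops, split
   at sharp corners (> 60° turn) where the cutting plane changes, and
   each planar sub-loop is closed by a fan of triangles about its
   centroid (plus the planar corner polygon when three or more cut planes
   meet a loop). Because the fill is a pure function of the boundary
   loop, identical loops — the unchanged wall of a well-registered pair —
   are always filled identically, so the volume difference cancels
   everywhere except the occlusal change.
3. **Volume difference.** Each closed part's volume is the divergence-
   theorem sum of signed tetrahedra; wear = V(T0 part) − V(T1 part),
   positive for substance loss.

## Exactness contracts

The nearest-point query is exact, not approximate: a kd-tree over
centroids of subdivided triangles only *prunes* candidates, with the
distance to the nearest mesh vertex as a certified upper bound, so the
result provably equals a brute-force scan over all triangles (tested
against an independently coded oracle). Watertightness is topological
(every directed edge paired with its reverse); volume computation refuses
non-watertight input, naming the boundary-edge count.

## The synthetic crown generator

Synthetic crowns stand in for scanned plaster teeth. Each crown is a
tapered wall (gingival rim exactly on z = 0, closed by a flat fan) with
an oval cross-section, a slight buccal bulge, an occlusal table with 2
(premolar) or 4 (molar) Gaussian cusps around a central fossa, and seeded
smooth pseudo-random relief. Key defaults, chosen once as a realistic
premolar/molar scale:

| parameter | premolar | molar | why |
|---|---|---|---|
| base radius | 4.2 mm | 5.2 mm | typical posterior crown widths (8–10 mm) |
| crown height | 7.5 mm | 7.0 mm | typical clinical crown heights |
| cusp height | 1.6 mm | 1.5 mm | cusp relief above the occlusal table |
| ovality | 0.09 | 0.05 | buccolingual > mesiodistal width |
| buccal bulge | 0.05 | 0.05 | breaks the 180° crown symmetry |
| surface relief | 0.12 mm, λ 3–6 mm | same | anatomical ridges/grooves |
| mesh resolution | 17 000 faces | same | matches scanned-crown tessellation |

The relief amplitude matters more than it looks: a smooth tapered body is
a degenerate registration target on which trimmed ICP can slide
helically (rotate about the crown axis while translating down the taper)
at almost no cost. Real crowns forbid this through their ridge/groove
anatomy; the 0.12 mm relief reproduces that property, and the ovality
and bulge remove the rotational and 180° symmetries.

Wear is applied in the upright crown frame with truth recorded exactly:

* **Occlusal grinding** presses all vertices above `z_max − depth` down
  onto a seeded undulating surface (amplitude ≤ 50 µm and ≤ depth/4, so
  the worn table is not perfectly planar but stays below the smallest
  wear step). Topology is untouched, so the mesh stays watertight, and
  the removed volume is the exact difference of enclosed volumes.
* **Lateral patches** displace vertices within the footprint radius
  inward along their normals by a cosine bump — C¹ at the rim, peak depth
  at the centre (closed-form removed volume `D·ρ0²·(π/2 − 2/π)` on a flat
  face, used as the test oracle). Nominal depths 0.100–0.250 mm and
  extents 3–5 mm.

T1 is then displaced by a seeded rigid transform (≤ 30°, ≤ 10 mm)
emulating an independent scan session; its inverse is the recorded true
alignment, which is exactly what superimposition on intact adjacent
structures would deliver — the gold standard needs no gingiva model.

The study replica enumerates 18 premolars + 18 molars, wear depths
cycling 0.5/1/2 mm (six per depth per type), half of each type labelled
"crowded" and realised as a seeded 5–15° crown-axis tilt (a surrogate: a
single crown cannot reproduce neighbour-tooth occlusion, only a
systematically non-axial pose).

### What the generator does not emulate

No scanner noise, no segmentation artefacts, no gingival margin change,
no neighbouring teeth, no anatomically faithful fissure patterns. The
synthetic T1 is *exactly* T0 outside the worn regions, so registration on
unchanged surface can converge to machine precision — real data would
floor at scanner accuracy (tens of µm). Passing tests therefore
demonstrate the pipeline's algorithmic correctness and its robustness to
the modelled changes, not its performance under scanner error.

## The manual-approximation surrogate

Every real registration is preceded by the operator roughly dragging the
crowns together. The surrogate is the true alignment degraded by a seeded
rotation of up to 5° about the crown centroid plus up to 0.5 mm of
translation. The measured basin of attraction of the trimmed ICP on these
crowns is about 0.7 mm laterally (a quarter of the relief wavelength —
beyond that the point-to-plane objective decorrelates from the relief
phase and local minima appear), and a visual overlay of two same-tooth
crowns comfortably achieves half a millimetre, so the surrogate sits
inside both. The study runner additionally emulates "the registration
was applied repeatedly until the minimum possible distance was reached":
up to three independent manual-approximation draws per measurement, the
lowest-RMS result winning, stopping early once the fit is numerically
perfect.

The user-defined overlap of setting C is replaced by a deterministic grid
search (0.15–0.80, step 0.05): each candidate overlap gets a full
registration (warm-started from a shared overlap-0.45 fit) and the pose
minimising a comparable stability score — the RMS over the fixed 15 %
closest correspondences — wins, ties going to the smallest overlap. This
is documented as a surrogate for the operator's visual criterion, not a
claim of equivalence.

## Numerical choices

* Vertex merge tolerance on load: 1e-6 mm (binary STL repeats vertices
  per facet; far below scanner accuracy).
* Changed-vertex threshold for plane placement: 50 µm — above plausible
  scanner noise, below the smallest simulated patch depth (100 µm).
* Sharp-corner threshold: 60° boundary turning angle; plane-plane
  intersections on crowns turn by nearly 90°. An in-plane corner (e.g.
  the square corner of a single flat cut) does not split a loop: segments
  are tagged with the cut planes containing them and cyclically adjacent
  segments sharing a plane are merged.
* ICP convergence tolerance 1e-6 mm on the trimmed-RMS improvement; 50
  iterations per round, up to 5 rounds; 100 % vertex sampling (sampling
  refers to reference vertices, not a denser surface resampling).
* Loop planarity tolerance for fills: 1e-6 mm; cut vertices are snapped
  exactly onto their plane, and coincident cut vertices (several mesh
  edges meeting a plane corner) are welded at 1e-12 mm.
* Degenerate inputs: all-tied Friedman tables report statistic 0, p 1,
  with a degeneracy flag (the tie correction would divide by zero);
  all-zero Wilcoxon differences report p 1; a constant non-zero repeat
  offset reports a systematic-error p of 0.
* Supported slicing arrangements: one gingival plane plus side planes
  whose corner polygon lies in the gingival plane (the 1–3 plane dental
  case). Arrangements whose corner polygon lies in no cut plane (three
  mutually intersecting planes chopping a corner) are rejected rather
  than mis-filled.

## Problem sizes used by the test and study harness

Crowns in the study replica and test suite are generated at 6 000 faces
(unit-geometry tests use 2 000–3 000), the package's desk-scale choice;
the generator default of 17 000 faces matches scanned-crown tessellation
and is used by the acceptance benchmark. The study harness runs the GS,
PC_A, CC_B and CC_D techniques over all 36 teeth; the full six-technique
battery, including the two grid-search (user-overlap) techniques, is
exercised on a 6-tooth replica.

## Known limitations

* The trimming interpretation of "estimated overlap of meshes" and the
  boundary-rejection interpretation of "exclude overhangs" are the
  standard trimmed-ICP readings of those controls; the original
  software's exact semantics are not published.
* Mesial/distal slicing planes are supported by the slicing/filling
  engine but the automatic plane proposer only emits the gingival plane:
  on single synthetic crowns a straight gingival cut always suffices or
  the case is genuinely unseparable (an error). Real casts with uneven
  margins would need the multi-plane proposal a human operator performs.
* Technique errors on noiseless synthetic data are much smaller than on
  scanned plaster models; the study replica supports bounds and
  orderings, not the reproduction of printed medians.
* The crowding stratum is an axis-tilt surrogate; effects mediated by
  neighbouring teeth cannot appear.
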