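# ceph3d

Three-dimensional landmark-based craniomaxillofacial and airway
cephalometry, with the rater-reliability analysis used to validate such a
system. It is written for orthodontic/orthognathic researchers and
engineers who work with manually or automatically digitised CT landmarks
and need (a) a complete, auditable measurement schema and (b) a rigorous
intra-/inter-examiner agreement protocol.

## What it implements

* **126-landmark schema** in the LPS (left–posterior–superior) frame,
  grouped into cranial (28), mandibular (25), teeth (20), soft-tissue (48)
  and airway (6) regions; the posterior nasal spine `alv(PNS)` is shared
  between the cranial and airway sets. Sessions are read from 3D Slicer
  markups (FCSV or JSON, RAS converted on read) or plain CSV.
* **Seven reference planes**: the Frankfort horizontal FH is the ordinary
  least-squares plane through the four orbitale/porion points (superior
  coordinate regressed on the axial footprint); SP through nasion and
  basion ⊥ FH; HP through nasion ∥ FH; CP through nasion ⊥ FH, SP; the
  mandibular plane through gnathion and both gonions; the occlusal plane
  through the incisal-edge midpoint and both first-molar cusps; and the
  true vertical line plane through subnasale ⊥ FH, SP.
* **78 measurement parameters** — 42 skeletal (23 angular such as SNA, SNB,
  ANB, FMA, Y-axis; 19 linear such as Overbite, Overjet, N-Me), 27
  soft-tissue (9 angular, 18 linear, including the signed profile distances
  to the TVL) and 9 upper-airway parameters. Airway cross-sectional areas
  come from planar mesh sections on a 1 mm grid between the `alv(PNS)`, `u`
  (uvula) and `c3` planes; volumes are exact plane-clipped mesh volumes via
  the divergence theorem.
* **Reliability**: ICC(A,1) — the single-measurement, absolute-agreement,
  two-way random-effects intraclass correlation —

      ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),

  with 95% confidence intervals by the F-based construction with
  Satterthwaite degrees of freedom, four-band classification
  (poor < 0.5 ≤ moderate ≤ 0.75 < good ≤ 0.9 < excellent) and two-condition
  flagging (ICC < 0.75; or ICC ≥ 0.75 with lower CI bound < 0.50), applied
  per landmark coordinate axis and per parameter over a 2-examiner ×
  2-session study design.
* **Synthetic data**: a mirror-symmetric parametric head template, a
  variance-components simulator of the 2×2 labeling study, and airway
  phantom meshes with closed-form areas and volumes.

## Worked example

```python
import ceph3d as c3

head = c3.make_template(0)                      # complete 126-landmark set
planes = c3.build_reference_planes(head)
values = {v.parameter: v.value for v in c3.evaluate_all(head, planes)}
print(f"SNA  {values['SNA|°']:.1f}°   ANB  {values['ANB|°']:.1f}°   "
      f"Overbite {values['Overbite|^d']:.1f} mm   "
      f"Go Canting {values['Go Canting|°']:.2e}°")
```

prints

```
SNA  82.9°   ANB  1.7°   Overbite 1.6 mm   Go Canting -8.91e-16°
```

— plausible Class-I skeletal values, and an exactly null gonial canting
because the template is mirror-symmetric by construction. A full simulated
reliability study runs from the shell:

```bash
ceph3d simulate --subjects 15 --seed 1 --out-dir study/
ceph3d reliability --manifest study/manifest.csv --out-dir reports/
```

which writes `landmark_icc.csv` (127 landmark rows × L/P/S axes ×
inter/intra conditions), `parameter_icc.csv` (78 rows per condition),
`flags.csv` and a markdown table in the `0.94 [0.48,0.99]` style.

## Scope notes

DICOM conversion, voxel resampling, automatic landmark detection and
nasal-cavity/sinus segmentation are out of scope: the package starts from
named 3-D points (plus an optional airway surface mesh) and ends at
measurements and reliability tables. See `docs/methods.md` for the model
details, conventions and known limitations.
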