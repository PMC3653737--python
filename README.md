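# contourbench

Quantitative comparison of radiotherapy structure sets drawn by multiple
human observers and by automatic (atlas-based) segmentation.

In multicentre radiotherapy trials, participating centres contour the same
benchmark CT cases — prostate clinical target volume (CTV), bladder,
rectum — and the trial QA team must quantify how much the submitted
structures disagree with each other and with an automatic segmenter.
`contourbench` implements that comparison pipeline for structures stored
as stacks of closed planar polygons on axial slices: slice-stack
volumetry, volume/overlap statistics, superior–inferior extent
differences, fiducial-based recovery of coordinate frames corrupted by
planning-system export, and per-vertex surface maps of spatial
disagreement. A synthetic pelvic cohort generator provides end-to-end
benchmarking data with known ground truth.

## The statistics

For an observer structure with volume $V_{Obs}$, a reference
(auto-segmented) structure with volume $V_{Ref}$, and their boolean
intersection $V_{Obs\cap Ref}$:

$$\Delta V = 100 \times \frac{V_{Obs} - V_{Ref}}{V_{Ref}}\,,\qquad
DSC = \frac{2\,V_{Obs\cap Ref}}{V_{Obs} + V_{Ref}}\,,\qquad
I_{Obs} = \frac{V_{Obs\cap Ref}}{V_{Obs}}$$

Volumes are slab sums, $V = \sum_k A_k\,\Delta z$, with per-slice polygon
areas $A_k$ from the shoelace formula and boolean per-slice clipping for
intersections and unions. Axial extent differences
$z_{Sup,Obs}-z_{Sup,Ref}$ and $z_{Inf,Obs}-z_{Inf,Ref}$ are positive when
the observer's structure reaches a more superior slice. The surface map
assigns to every vertex of the reference structure the mean, over
observers, of the closest observer-contour distance on that slice and
each adjacent slice. All lengths are cm, volumes cm³.

## Worked example

A bundled table from a published two-patient benchmarking exercise lists,
per observer, the measured volume triples and the derived statistics. For
the high-risk case CTV, observer H measured $V_{Obs}=50.2$ cm³ against the
auto-segmented $V_{Ref}=54.0$ cm³ with $V_{\cap}=40.3$ cm³:

```python
>>> from contourbench import dsc, intersection_fraction
>>> round(dsc(50.2, 54.0, 40.3), 2)
0.77
>>> round(intersection_fraction(40.3, 50.2), 2)
0.80
```

i.e. the two structures overlap on 77% of their mean volume and 80% of
the observer's volume is inside the reference — good agreement. The gross
outlier observer J (158.8 cm³, three times the reference volume) scores
`dsc(158.8, 54.0, 54.0) → 0.51` despite fully containing the reference.
Running `python examples/reproduce_published_tables.py` recomputes all
102 derived overlap cells of the bundled tables: 97 match the printed
values exactly at two decimals and the remaining five differ by one unit
in the last printed digit (the printed inputs are themselves rounded).

A full synthetic run (`python examples/synthetic_benchmark.py`) simulates
11 observers and a volume-biased auto-segmenter, realigns every scrambled
coordinate frame from skin fiducials (residual ~1e-16 cm), and prints the
CTV comparison table, e.g.:

```
observer role  V_obs_cm3  dV_pct  V_int_cm3  DSC    I  dz_sup_cm  dz_inf_cm
       A  CTV       28.0   120.7       12.7 0.62 0.45        0.6      -1.50
     ...
    mean  CTV       26.7   110.1       12.6 0.64 0.48        0.6      -1.64
      sd  CTV        2.8    22.2        0.1 0.04 0.05        0.0       0.21
```

Every observer's CTV exceeds the automatic one by ~100% ($\Delta V>0$:
the atlas bias), overlap is moderate (DSC ≈ 0.6), and observers extend
the prostatic apex 1.5–2 cm more inferiorly (negative `dz_inf`).

Other examples: `examples/surface_disagreement_map.py` (per-vertex maps,
undefined bands where observers stop contouring) and
`examples/fiducial_realignment.py` (coordinate-frame recovery).

## Command line

```sh
contourbench simulate --out cohort --seed 7 --n-observers 11
contourbench align --reference cohort/reference.json --out aligned cohort/observer_*.json cohort/autoseg.json
contourbench report --reference aligned/aligned_auto.json --out report --exclude J:CTV aligned/aligned_*.json
```

`report` writes one metrics CSV per role (with mean/SD footer and
explicit missing-value rows), one surface-map CSV per role sharing a
global colour-scale maximum, and a JSON summary.

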