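# Study file format (version 1)

A study is a single JSON document bundling the planar contours of one
subject at one cardiac phase with the imaging geometry needed to place them
in the patient coordinate system (DICOM LPS, mm).

```json
{
 "format": "lheart-study",
 "version": 1,
 "planes": [
  {
   "plane_id": "sax05",
   "view": "sax",
   "position": [-67.555, -68.455, -8.0],
   "row_dir": [1.0, 0.0, 0.0],
   "col_dir": [0.0, 1.0, 0.0],
   "spacing": [1.43, 1.43]
  }
 ],
 "contours": [
  {
   "plane_id": "sax05",
   "label": "LV",
   "closed": true,
   "points": [[41.25, 33.0], [41.0, 33.5], ...]
  }
 ]
}
```

## `planes[]`

| field      | type        | meaning |
|------------|-------------|---------|
| `plane_id` | string      | unique key referenced by contours |
| `view`     | enum        | `sax`, `2ch`, `3ch`, `4ch` |
| `position` | [x, y, z]   | patient coordinates (mm) of pixel (0, 0) — DICOM (0020,0032) |
| `row_dir`  | unit 3-vec  | direction of increasing `u` — first triple of (0020,0037) |
| `col_dir`  | unit 3-vec  | direction of increasing `v` — second triple of (0020,0037) |
| `spacing`  | [Δu, Δv]    | mm/pixel; note `Δu = PixelSpacing[1]`, `Δv = PixelSpacing[0]` |

`row_dir`/`col_dir` must be unit length and orthogonal within 1e-6 (they
are re-normalized inside that tolerance, rejected beyond it); `spacing`
must be positive.

## `contours[]`

| field      | type    | meaning |
|------------|---------|---------|
| `plane_id` | string  | must match a plane entry (dangling ids are an error) |
| `label`    | enum    | `LV`, `LA`, `AO`, or `MERGED` for the bifurcation slices where the structures cannot be separated |
| `closed`   | bool    | closed loop (first point is implicitly connected to the last; do not repeat it) |
| `points`   | [[u, v]] | ordered 0-based pixel coordinates; ≥ 3 points when closed, no two consecutive points identical |

A contour point maps to the patient frame as
`p = position + u·Δu·row_dir + v·Δv·col_dir`.

Writing is deterministic (plane entries sorted by id, coordinates rounded
to 9 decimals), so identical studies produce byte-identical files.
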