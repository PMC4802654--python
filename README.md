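# hfigures

Radial visualization of grouped health measurements over time, exported as
self-contained SVG.

Clinicians, health coaches and self-trackers accumulate measurements —
blood pressure, lab panels, sleep, activity scores — that are hard to read
as tables. `hfigures` draws them on a radial canvas: every measurement gets
an angular slot, its value is mapped to a radius so that the recommended
range [rec_min, rec_max] always lands on a fixed annulus (the *recommended
band*), and one closed polygon per time snapshot joins all the points. The
polygon's shape gives the overall situation at a glance; overlaying several
snapshots (older ones in lighter colors) shows how it has evolved, for
example before and after a coaching program. No overall score is computed —
the data is shown "as is".

## The model

* **Slots.** A dataset with N measurements in G groups divides the circle
  into N + G equal slots of 2π/(N+G) radians: one per measurement plus one
  spacer per group, so categories are visibly separated sectors. Angle 0 is
  12 o'clock, increasing clockwise.
* **Radius.** A value v with recommended range [a, b] plots at
  r(v) = r_inner + (v − a)·(r_outer − r_inner)/(b − a), clamped to the
  plottable ring [r_min, r_max]; so r(a) = r_inner, r(b) = r_outer exactly,
  and out-of-range values sit visibly inside or outside the band.
* **Traffic lights.** A sample is green inside the recommended range,
  yellow between a recommended bound and the corresponding warning bound,
  red beyond it (or outside the recommended range when no warning bound is
  declared). Older snapshots are whitened channel-wise by a fixed fraction
  per age step.
* **Labels.** A measurement label is anchored at radius
  r_label = max_i(r_i) + margin over its sample radii, so it clears its own
  circles; collisions between labels are resolved by quadrant stacking —
  per canvas quadrant, labels are processed from the horizontal axis
  outward and shifted vertically until every pair is separated.
* **Output.** One SVG 1.1 document styled entirely through presentation
  attributes — no scripts, no stylesheets, no external references — so the
  file drops unchanged into articles, posters or other applications, and
  identical inputs produce byte-identical files.

Timestamps are Unix epoch seconds (GMT). The input dialect is documented in
`src/hfigures/data_source.schema.json`.

## Worked example

```python
import math
from hfigures import (
    generate_minimal_example, build_angular_layout, normalize_value,
    classify_value, GeometryConfig, RenderOptions, render_figure,
    write_svg, epoch_to_utc,
)

ds = generate_minimal_example()          # "Blood Pressure": Systolic, Diastolic
geo = GeometryConfig()                   # 1200x1200 canvas, band at 280..380 px
layout = build_angular_layout(ds)
print(f"slot angle: {math.degrees(layout.slot_angle):.1f} degrees")
for g, m in ds.iter_measurements():
    angle = math.degrees(layout.measurement_angle[(g.label, m.label)])
    for s in m.samples:
        r = normalize_value(s.value, m, geo)
        status = classify_value(s.value, m).name.lower()
        date = epoch_to_utc(s.timestamp).strftime("%Y-%m-%d")
        print(f"{m.label:9s} {date}  {s.value:6.1f} {m.units}  ->  "
              f"r = {r:.1f} px, {status}  (angle {angle:.0f} deg)")

doc = render_figure(ds, RenderOptions(snapshot_targets=[0, 1]))
write_svg(doc, "figure.svg")
```

prints

```
slot angle: 120.0 degrees
Systolic  2015-01-09   132.0 mmHg  ->  r = 420.0 px, warning  (angle 60 deg)
Systolic  2015-02-12   118.0 mmHg  ->  r = 373.3 px, normal  (angle 60 deg)
Diastolic 2015-01-09    88.0 mmHg  ->  r = 420.0 px, warning  (angle 180 deg)
Diastolic 2015-02-12    79.0 mmHg  ->  r = 375.0 px, normal  (angle 180 deg)
```

Two measurements in one group make 3 slots of 120°. The January readings
(132/88 mmHg) exceed their recommended ranges — they plot outside the band
(r > 380 px) as yellow circles — while the February readings fall inside it
as green circles: the patient improved. `figure.svg` holds two polygons
(one per date, the older one lighter) and four circles.

The same pipeline runs from the shell, including a nine-group synthetic
"coached patient" generator for experimenting without any data files:

```sh
hfigures fixture patient.json --seed 1
hfigures render patient.json figure.svg
hfigures render --validate-only patient.json
```

## Scope

The library reads JSON only (no XML) and never fetches data remotely;
browser interactivity (zooming, hover pop-ups) is out of scope — label
visibility is a render option, and the figure's shape never depends on it.
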