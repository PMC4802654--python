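# Methods

## Data model

A dataset is a tree: groups → measurements → samples. Each measurement
carries a closed recommended range `[rec_min, rec_max]` (`rec_min <
rec_max` is required; one-sided recommended ranges are not supported,
because the radius normalization is defined on a closed band) and optional
warning bounds with `warn_min ≤ rec_min ≤ rec_max ≤ warn_max` — either
side may be present independently, which models quantities where only one
direction of excursion is dangerous (e.g. a floor on a fitness score, a
ceiling on salt intake). Samples are `(timestamp, value)` pairs with
timestamps in Unix epoch seconds interpreted strictly as GMT; conversion
never consults the host timezone, so 1420798224 is 2015-01-09 10:10:24 GMT
on every machine. Fractional timestamps are truncated with a warning;
unsorted sample arrays are sorted on parse with a warning rather than
rejected.

The JSON dialect (`data_source.schema.json`) uses explicit keys —
`recommended: {min, max}`, optional `warning: {min?, max?}`,
`samples: [{timestamp, value}]` — chosen over positional or abbreviated
forms so that validation errors can name an exact path
(`groups[0].measurements[1].samples[2].value`). Validation is performed by
the parser itself rather than a schema engine; the schema file is the
machine-readable contract and doubles as documentation. Serialization
emits warning keys only where bounds exist, so parse∘serialize is the
identity on every valid dataset.

### Snapshots

A snapshot is one sample per measurement at one logical time point; it is
the unit that renders as one polygon. Two alignment modes exist because
real time series rarely align perfectly:

* `by_index` (default, strict): requires every measurement to have the
  same sample count and takes the i-th sample everywhere. Errors list
  every (group, measurement, count) triple so a ragged file can be fixed
  in one pass.
* `nearest_time` (tolerant): per measurement, the sample minimizing
  |timestamp − target|, earlier sample winning ties.

The synthetic fixtures share timestamps across all measurements, so the
two modes agree on them.

## Radius normalization

Values map to radii by a piecewise-linear, monotone map: the recommended
interval maps affinely onto the band annulus `[r_band_inner,
r_band_outer]`, and outside the interval the same pixels-per-unit slope
continues until clamped to the plottable ring `[r_min, r_max]`. This is
the simplest monotone map that makes the band boundaries exact, keeps
in-band geometry independent of how far outliers stray, and leaves
out-of-range points visibly off the band (clamping bounds the damage of
extreme outliers instead of rescaling everyone else). Larger values always
plot at larger radius — low excursions fall inside the band, high ones
outside; one fixed convention keeps different figures comparable.

Band exactness is floating-point exact at the bounds (the formula
evaluates to `r_band_inner` and `r_band_outer` with no cancellation);
tests assert it at 1e-9 relative tolerance.

## Traffic-light classification

The recommended interval is closed: a value exactly at a bound is normal,
matching the inclusive clinical reading of "within recommended". A value
outside the recommended range but inside a declared warning bound is a
warning, the bound itself included (ties always go to the less severe
class). Beyond a declared warning bound — or outside the recommended range
on a side with no warning bound — is critical. This partitions the real
line: every finite value gets exactly one status.

## Snapshot aging colors

Older snapshots are whitened channel-wise: with lighten step s and age a,
each RGB channel c becomes 255 − (255 − c)(1 − s)^a, rounded once at the
end. Age 0 (the newest rendered snapshot) is the palette color unchanged.
Channel-wise linear mixing was chosen over HSL manipulation because it is
deterministic, implementation-independent integer arithmetic with no
colorspace round-trip; perceived lightness increases strictly with age for
any s > 0. The default step 0.35 keeps two or three generations clearly
distinguishable without washing out; the default palette
(#2ca25f/#f1c40f/#e74c3c) uses conventional traffic-light hues and is
fully overridable.

## Angular layout

N measurements in G groups produce N + G equal slots (one spacer after
every group, including the last — the only reading under which the N + G
arithmetic closes the circle). Slots are assigned in dataset order,
clockwise from 12 o'clock; a measurement sits at its slot center, and a
group's arc spans its measurement slots exclusive of spacers. Start angle
and direction are conventions the data does not determine; they are fixed
and documented so figures are comparable.

## Label placement

A label's anchor radius is the maximum of its measurement's rendered
sample radii plus a configurable margin (default 12 px), so a label can
never sit on its own circles even when an out-of-range sample is pushed
far out. Box sizes are estimated from fixed per-character metrics
(defaults: 7 px/character, 14 px/line) rather than font metrics: the
package writes documents without a rendering engine, and fixed metrics
keep output identical on every platform. The estimate is conservative for
proportional fonts at the default size.

De-collision is quadrant stacking: per canvas side (anchors exactly on the
vertical axis count as right), labels are processed in order of angular
distance from the horizontal axis (ties broken by dataset order) and
shifted vertically — up in the upper half, down in the lower — by the
minimum amount that gives every already-placed box on that side a vertical
center-to-center gap of at least the mean of the two box heights plus the
margin. Checking against all placed boxes on the side, not only the
immediately preceding one, is what makes the no-overlap guarantee hold
where the four quadrant chains meet the horizontal axis. Horizontal
positions never change (right-side boxes extend rightward from the anchor,
left-side leftward, so the two sides cannot collide across the vertical
axis), and vertical order within a quadrant is preserved. If a stack runs
off the canvas the placement fails with an error suggesting a larger
canvas or hidden labels; with the default 1200 px canvas roughly 20 labels
fit per side, and the dense-label checks in the test suite use a 2400 px
canvas so 40 one-sided labels always fit.

## Rendering

Paint order: recommended-band annulus, group arcs and group labels (always
drawn — sectors stay visible whatever the label setting), snapshot
polygons oldest-to-newest, sample circles oldest-to-newest, measurement
labels. The newest snapshot is therefore never occluded. Polygons are
stroke-only in a neutral dark tone (lightened with age); status colors
live on the circles, keeping the traffic-light semantics point-local. One
closed polygon per snapshot connects all measurements in angular order,
crossing group gaps. Group labels are horizontal text at the arc
mid-angle just outside the ring; curved text would require path/font
machinery and buy little at nine groups.

Documents are SVG 1.1 with styling exclusively via presentation
attributes: no `<script>`, no `<style>`, no external references, `class`
attributes carried purely as inert metadata for testing and downstream
tooling. Coordinates are written with at most two decimals and attribute
order is fixed, so identical inputs yield byte-identical files and
golden-file testing is sound. The viewBox equals the canvas; zooming is a
viewer concern and no view state is stored.

## Synthetic fixtures

`generate_modeled_patient` emulates a coached patient: nine categories
(blood pressure, physical activity, body composition, sleep, fitness, lab
tests, nutrition, drugs, emotional wellbeing) expanding to 34
measurements. Reference ranges are conventional adult values embedded as
one table in code purely as test scaffolding — they carry no clinical
claim. First-snapshot values are uniform over the recommended range
extended by 30 % of its width on both sides, guaranteeing a mix of
normal/warning/critical circles in rendered fixtures; each later snapshot
moves a value toward the band center by the `improvement` fraction
(default 0.5, two snapshots by default — a before/after-coaching pair)
plus Gaussian noise with σ = 2 % of the range width. Timestamps are
shared across measurements and strictly increasing, anchored at the
documented example date (2015-01-09) with ~34-day spacing. Generation is a
pure function of (seed, n_snapshots, improvement, include_warning_ranges).

What the generator does not emulate: missing samples, ragged series,
measurement-specific noise models, device artifacts, or correlated
improvements across categories. Tests passing on these fixtures therefore
demonstrate geometric and structural correctness of the pipeline, not
robustness to messy real-world exports — the parser's warning/sorting
behavior and the `nearest_time` mode are the concessions to that
messiness.

## Problem sizes and numerical choices

Property-style suites run at 100–200 random datasets (up to 12 groups × 10
measurements) and 10⁴ random normalization draws; the whole suite
completes in a few seconds on one CPU. Angular arithmetic is tested to
1e-9 absolute; floating comparisons elsewhere use 1e-9 relative. Epoch
round-trips are property-tested over [0, 2³¹). Degenerate inputs
(`rec_min == rec_max`, empty datasets, empty label text, negative radii or
timestamps) are rejected at construction or call time with descriptive
errors, never silently corrected — except sample ordering and fractional
timestamps, which are corrected loudly, because both occur routinely in
real exports and have one obvious safe fix.

## Command-line interface

`hfigures render` and `hfigures fixture` expose exactly the knobs the
library defines (snapshot selection, canvas size, band radii, label
margin, label flags, seed) and nothing more. Exit codes separate usage
errors (2), parse/validation errors (3), render errors (4) and I/O errors
(5) so scripts can branch on the failure class; `--validate-only` checks a
file without writing anything.

## Known limitations

* No XML input; no remote data retrieval.
* One-sided recommended ranges are unsupported (warning bounds may be
  one-sided).
* Label box estimation ignores actual glyph widths; pathological fonts
  could overflow the estimated boxes.
* Very long measurement lists on a small canvas fail label placement
  rather than shrinking text; the caller chooses between a larger canvas
  and hidden labels.
* The label stacking resolves overlaps vertically only; extremely wide
  boxes at near-identical angles can be pushed far from their anchors.
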