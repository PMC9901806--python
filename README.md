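# filatrack

Detection, segmentation and frame-to-frame tracking of curvilinear
filaments (e.g. cytoskeletal stress fibers, microtubules, intermediate
filaments) in 2D fluorescence microscopy images and time-lapse stacks.

The toolbox covers:

- **preprocessing** — image/stack loading (TIFF, PNG), a pluggable,
  JSON-serializable filter pipeline, and binarization (global Otsu,
  local mean, fixed threshold).
- **sensing** — the circle-mask *width map* (per-pixel largest disk
  diameter fitting the foreground), straight-line filament scanning, and
  the per-pixel orientation field.
- **curve_tracer** — curved-filament tracing by seeded bidirectional
  forward search over the width map: directions probed at 3°·φ
  increments, steps of at most `l_str` pixels, candidates ranked longest
  first and validated against the orientation field (conflicting
  segments are discarded or shortened).
- **features** — per-filament descriptors (center, length, width, angle,
  curvature), cell-shape descriptors, the length-weighted nematic order
  parameter, and pixel-wise / object-wise detection comparisons.
- **tracking** — single-filament tracking via unbalanced optimal
  transport: filaments are cut into ~10 px fragments, fragments of
  consecutive frames are matched by an exact transportation LP with
  dummy sinks (cost `4·d_l² + d_φ²`, locality bound `d_max`), and links
  are consolidated into lifelines with birth/death/persistence.
- **cell_events** — bounding-box area tracking: overlap-scored matching
  map, Start/Alive/Split/Fusion classification, and post-processing that
  rewrites fusion-then-split into Touch/DeTouch without interrupting
  lifelines.
- **synthetic** — ground-truthed stroke images (lines, circular arcs,
  quadratic Béziers with closed-form length/curvature), drifting stroke
  movies and scripted blob movies used as test oracles.
- **cli / batch** — a `filatrack` command with `trace`, `batch`,
  `track`, `events`, `fixtures`, `compare` and `init-settings`
  subcommands, versioned JSON settings files, and deterministic, atomic
  CSV outputs.

## Usage

```sh
# write a default settings file (edit as needed)
filatrack init-settings settings.json

# detect filaments in one image or stack; CSVs go to out/
filatrack trace cell.tif --settings settings.json --out out/

# process every image in every sub-folder, results stored in place
filatrack batch experiments/ --settings settings.json

# regenerate the synthetic fixture corpus
filatrack fixtures --out fixtures/ --seed 0

# straight vs curved detection comparison (pixel- and object-wise)
filatrack compare cell.tif --out comparison.json
```

Library use:

```python
import filatrack as flt

img = flt.load_image("cell.tif")
mask = flt.binarize(img)
filaments = flt.trace_filaments(mask, flt.TracerSettings(l_min=30, l_str=10))
```

Key tracer parameters: `l_min` (minimal filament length), `l_str`
(straight-piece step length), `phi_diff` (multiplier of the 3° probing
increment — raise it for strongly curved structures), `alpha_tol`
(orientation-conflict tolerance, default 20°).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: width-map
equivalence with a brute-force oracle, curve recovery on 30 ground-truthed
stroke fixtures, the orientation-field veto thresholds, transport-LP
oracle equivalence and locality, tracking persistence, scripted
cell-event recovery, comparison-operator correctness and bit-identical
batch determinism.

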