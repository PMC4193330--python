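# teardrop

A recurrent network model of **figure-ground segregation** in the primate
ventral stream, for computational neuroscientists studying how visual
cortex tells the inside of a figure from its background.

The model's core idea is that *interior enhancement* — the elevated firing
of a neuron whose receptive field (RF) lies inside a figure — is a code for
the figure's **medial axis** (skeleton), computed by exploiting the natural
*jitter* of RF sizes and centres:

* **curved-contour cells** (model V4) group oriented edge energy into arcs
  of circles, 8 arcs × 7 radii per position;
* **convex cells** (model PIT) integrate those arcs over annular
  on-surround RFs, so a cell fires when boundary contours fall on the ring
  around its centre — a point detector for the medial axis, with a strong
  preference for *closed* contours;
* **teardrop cells** (model AIT) read ordered ramps of convex cells whose
  RF sizes increase linearly along one of 8 integration directions;
  agreement across directions is evidence for boundary **closure**, and is
  fed back to enhance convex activity on the medial axis and suppress it
  elsewhere, while a coarse-to-fine **recurrent circuit** lets large-RF
  cells veto spurious medial responses inside concavities.

All layers evolve by shunting membrane dynamics
`dx/dt = −A·x + (B − x)·E − (D + x)·I`, integrated to equilibrium.
Performance is quantified with three normalized-contrast indices — the
in-out index `IOI = (Ā_fig − Ā_gnd)/(Ā_fig + Ā_gnd)`, the medial-axis index
`MAI = (Ā_med − Ā_int)/(Ā_med + Ā_int)` (activity within 1 px of the
skeleton vs the rest of the interior), and the boundary index `BI` — plus
the kurtosis of the per-RF-size response profile.  The stimulus module
generates the standard display families (rectangles, C-shapes, crosses,
square-texture arrays, seeded random-block figures) with ground-truth
masks and skeletons, and either feedback pathway can be lesioned.

## Worked example

```bash
python examples/run_square.py
```

```
display: square (27 px)
converged after 47 steps
dominant RF size: 4 (annulus radius 13.5 px, half-width 13.5 px)
peak position: (31, 31) (canvas centre is ~(31.5, 31.5))
MAI at dominant scale: 0.854
IOI: 0.982   BI: -0.079   kurtosis: 22.82
per-scale maxima: [0.013 0.013 0.016 0.704 0.013 0.002 0.   ]
```

The network's activity for a 27 px square collapses onto a single RF size —
the one whose annulus radius (13.5 px) equals the square's half-width —
with its peak at the centre, where the skeleton's diagonals cross.  The
MAI of 0.85 says the surviving activity at that scale is almost entirely
within one pixel of the skeleton; the IOI of 0.98 says essentially nothing
survives on the background; the high kurtosis says the population "agrees"
on one RF size.  Other entry points:

* `examples/medial_axis_gallery.py` — skeleton readout across all exemplar
  figures (C-shape, cross, texture array, thin bar, crescent, triangle);
* `examples/time_course.py` — the single-cell figure-vs-background
  paradigm on texture displays with identical pixels in the probe RF;
* `examples/lesion_sweep.py` — population indices under the four feedback
  conditions on random-block figures.

A thin CLI wraps the same library surface:

```bash
teardrop run --display c_shape --lesion none --out /tmp/c_run
teardrop sweep --set LC --subsample 10 --out /tmp/lc_sweep
teardrop generate --set crosses --out /tmp/crosses
```

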