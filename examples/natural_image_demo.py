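"""Optional demo: medial-axis readout on a user-supplied natural image.

Loads a grayscale image, thresholds it into a figure mask, and runs the
model on the resulting display.  This is a demonstration of the pipeline
on non-parametric input, not a natural-scene segmentation method: the edge
map is derived from the thresholded silhouette, so the demo works best for
images of bright objects on dark backgrounds (or vice versa, pass
--invert).

Usage:
    python examples/natural_image_demo.py path/to/image.png [--invert]
"""

import sys
import warnings

import numpy as np
from skimage.transform import resize

from teardrop import run
from teardrop.io import load_image
from teardrop.metrics import evaluate
from teardrop.stimuli import CANVAS, _display_from_mask

if len(sys.argv) < 2:
    sys.exit("usage: natural_image_demo.py IMAGE [--invert]")

img = load_image(sys.argv[1])
if "--invert" in sys.argv:
    img = 1.0 - img
img = resize(img, (CANVAS, CANVAS), anti_aliasing=True)
mask = img > (img.mean() + 0.5 * img.std())
if not mask.any():
    sys.exit("thresholding produced an empty figure; try --invert")

display = _display_from_mask(mask, "natural", {"source": sys.argv[1]},
                             image=img)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    traj = run(display)
    rep = evaluate(display, traj.final.convex, traj.lesion)

print(f"figure pixels: {int(mask.sum())} of {CANVAS * CANVAS}")
print(f"dominant RF size: {rep.peak_scale + 1}, peak at {rep.peak_position}")
print(f"IOI={rep.ioi:.3f}  MAI={rep.mai_dominant:.3f}  BI={rep.bi:.3f}")
print("per-scale maxima:", np.round(rep.per_scale_max, 3))
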