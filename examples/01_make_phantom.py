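"""Generate a synthetic ultrasound phantom pair and inspect its ground truth.

The pair mimics two intraoperative acquisitions of the same brain region:
the "moving" volume plays the pre-resection scan, the "fixed" one the scan
after some tissue was removed — a dark cavity with a bright rim that has
no counterpart in the moving volume — with a known smooth deformation and
independently drawn speckle between them.
"""

import numpy as np

from iusreg import make_pair
from iusreg.evaluation import mtre
from iusreg.experiments import phantom_spec_for_shape

spec = phantom_spec_for_shape(shape=(64, 64, 64), spacing=0.5, seed=7)
pair = make_pair(spec)

print(f"volume shape {pair.fixed.shape}, spacing {pair.fixed.spacing} mm")
print(f"beam cone covers {pair.beam_mask.count()} voxels "
      f"({100 * pair.beam_mask.count() / pair.fixed.data.size:.0f}% of grid)")
print(f"cavity (incl. rim) covers {pair.cavity_mask.count()} voxels")
print(f"true deformation: max |u| = {pair.true_field.max_magnitude():.2f} mm")

rep = mtre(pair.landmarks)
print(f"initial landmark error: {rep}")

from scipy import ndimage  # noqa: E402

beam = pair.beam_mask.data
cav = pair.cavity_mask.data          # interior plus the bright rim
interior = ndimage.binary_erosion(cav, iterations=3)
rim = cav & ~interior
print(f"mean intensity — cavity interior {pair.fixed.data[interior].mean():.1f}, "
      f"rim {pair.fixed.data[rim].mean():.1f}, "
      f"tissue {pair.fixed.data[beam & ~cav].mean():.1f}")
# Dark hole, bright wall, ordinary tissue in between: that hypoechoic
# cavity with its hyperechoic rim is what the segmentation stage learns
# and what the registration stage must exclude from its distance measure.
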