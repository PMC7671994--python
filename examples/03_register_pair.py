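"""Register a deformed phantom pair and measure landmark error reduction.

Runs the deformable stage (masked normalized-gradient-field distance with
curvature regularization, coarse-to-fine L-BFGS) on a cavity-free pair
with a known 4 mm deformation and reports the mean target registration
error before and after.
"""

import time

from iusreg import make_pair
from iusreg.evaluation import mtre
from iusreg.experiments import phantom_spec_for_shape
from iusreg.registration import deformable_register, transform_landmarks

pair = make_pair(phantom_spec_for_shape((64, 64, 64), 0.5, seed=11,
                                        cavity_radius=0.0,
                                        max_displacement=4.0))
before = mtre(pair.landmarks)
print(f"before registration: {before}")

t0 = time.time()
field, report = deformable_register(pair.fixed, pair.moving)
print(f"registration took {time.time() - t0:.0f}s")
for lev in report:
    print(f"  level {lev['level']}: {lev['iterations']} iterations, "
          f"stopped on {lev['stop_reason']}")

after = mtre(transform_landmarks(pair.landmarks, field))
print(f"after registration:  {after}")
print(f"error reduced to {100 * after.mean / before.mean:.0f}% of initial")
# The field maps each fixed-grid landmark into the moving volume's frame;
# the residual distance to its true counterpart is the registration error.
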