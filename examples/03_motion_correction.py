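"""Bulk-motion artifact and its sub-pixel correction.

A frozen (static) scene is given per-frame rigid jitter of up to 1.5 px.
Without correction the jitter masquerades as temporal dynamics and
inflates LIV severalfold; registering every frame to the central reference
frame by 1/10-px phase correlation restores the motion-free level.
"""

import numpy as np

from livoct import (Alveolus, CLASS_LABELS, MotionTrace, PhantomSpec,
                    build_label_map, compute_liv, inject_bulk_motion,
                    register_stack, simulate_timeseries)
from livoct.liv import stack_to_db

intensities = {"background": 0.05, "lumen": 0.3, "epithelium_high": 1.0,
               "epithelium_low": 1.0, "fibroblast": 0.5, "inclusion": 2.0}
spec = PhantomSpec(grid_shape=(96, 96, 1), class_intensity=intensities,
                   class_correlation={k: 1.0 for k in CLASS_LABELS},
                   alveoli=[Alveolus((48, 48, 0), 20, 6)],
                   noise_floor_mean=0.01, seed=3)
stack = stack_to_db(
    simulate_timeseries(build_label_map(spec), spec, n_frames=16, seed=3)[0],
    spec.noise_floor_mean)

rng = np.random.default_rng(9)
trace = MotionTrace(np.round(rng.uniform(-1.5, 1.5, (16, 2)) * 10) / 10)
jittered = inject_bulk_motion(stack, trace)
corrected, estimated = register_stack(jittered)

sel = corrected.valid.copy()
sel[:8] = sel[-8:] = False
sel[:, :8] = sel[:, -8:] = False
free = compute_liv(stack).liv[sel].mean()
jit = compute_liv(jittered).liv[sel].mean()
corr = compute_liv(corrected).liv[sel].mean()
print(f"mean LIV motion-free : {free:6.3f} dB^2")
print(f"mean LIV jittered    : {jit:6.3f} dB^2  ({jit / free:.1f}x inflated)")
print(f"mean LIV corrected   : {corr:6.3f} dB^2  ({corr / free:.2f}x)")
print(f"largest estimated shift: {np.abs(estimated.shifts).max():.1f} px")
# The corrected level should sit within a few percent of motion-free while
# the uncorrected stack reads several times too high.
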