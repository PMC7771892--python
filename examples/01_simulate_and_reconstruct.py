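"""Forward-simulate an FPM acquisition and reconstruct it.

Builds a resolution bar target, captures a noise-free low-resolution stack
under a 9x9 LED array, runs sequential Gauss-Newton phase retrieval, and
compares the recovered amplitude with the band-limited ground truth.
"""

import numpy as np

from fpmsda import (
    ReconSchedule,
    align_global_phase,
    band_limited_reference,
    exclude_hybrid_frames,
    led_grid,
    make_bar_target,
    reconstruct,
    simulate_lr_stack,
)
from fpmsda.metrics import compare_images

geometry = led_grid(9, pitch=5.0, array_height=60.0, wavelength=532.0, objective_na=0.16)
obj = make_bar_target(192, bar_periods=[16, 10, 6], pixel_size=0.27)

stack = simulate_lr_stack(obj, geometry, lr_shape=64)
labels = {lab: stack.labels.count(lab) for lab in ("BF", "DF", "HYBRID")}
print(f"simulated {len(stack)} frames: {labels}")

kept, removed = exclude_hybrid_frames(stack)
print(f"excluded {removed} hybrid BF/DF frames")

result = reconstruct(kept, geometry, ReconSchedule(n_iterations=10),
                     hr_shape=192, pixel_size=0.27)
truth = band_limited_reference(obj, geometry)
field = align_global_phase(result.field, truth)
ssim, mse = compare_images(np.abs(field), np.abs(truth))

print(f"synthetic NA {result.synthetic_na:.3f} "
      f"(objective 0.16 + max illumination {result.synthetic_na - 0.16:.3f})")
print(f"amplitude SSIM vs band-limited truth: {ssim:.4f}  (1.0 = perfect)")
print(f"residual, first -> last iteration: "
      f"{result.per_iteration_residual[0]:.3g} -> {result.per_iteration_residual[-1]:.3g}")
# With noise-free data the round trip recovers everything the sampled
# passbands transmit, hence SSIM close to 1 and a residual that collapses.
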