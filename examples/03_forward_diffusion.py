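"""Watch the forward process drift the clean image toward the corrupted one.

The marginal at step t is N(x + beta_t r, gamma^2 beta_t I) with
r = y - x, so the mean moves along the residual while the noise grows.
By the last step the state is the corrupted image plus noise — which is
why the reverse process only has a short distance to travel.
"""

import numpy as np

from mocoshift import (
    MotionConfig,
    PairedSample,
    PhantomConfig,
    ScheduleConfig,
    build_schedule,
    corrupt,
    forward_marginal_params,
    make_phantom,
    sample_forward,
)

img = make_phantom(PhantomConfig(size=64, seed=3))
y, _ = corrupt(img, MotionConfig.preset("heavy"), np.random.default_rng(1))
pair = PairedSample(x=img, y=y)
sched = build_schedule(ScheduleConfig())
rng = np.random.default_rng(0)

print(f"{'t':>3} {'beta_t':>8} {'|mean-x|':>9} {'|mean-y|':>9} {'std':>6}")
for t in (1, 5, 10, 15, 20):
    mean, std = forward_marginal_params(pair, sched, t)
    dx = float(np.linalg.norm(mean - pair.x))
    dy = float(np.linalg.norm(mean - pair.y))
    print(f"{t:>3} {sched.betas[t]:>8.4f} {dx:>9.4f} {dy:>9.4f} {std:>6.3f}")

state = sample_forward(pair, sched, 20, rng)
print(
    f"\nA draw of x_20 has range [{state.x_t.min():.2f}, "
    f"{state.x_t.max():.2f}] — the corrupted image buried in noise of "
    f"std {2 * np.sqrt(0.999):.2f}."
)
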