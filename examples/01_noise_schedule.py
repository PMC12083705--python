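"""Build the shifting schedule and inspect how its knobs shape it.

The schedule interpolates geometrically from beta_1 = (0.04/gamma)^2,
where the first diffusion state is statistically indistinguishable from
the clean image, up to beta_N = 0.999, where the state mean has moved
(almost) all the way to the corrupted image.  The growth exponent p
controls how early the noise arrives.
"""

import numpy as np

from mocoshift import ScheduleConfig, build_schedule, noise_level

train = build_schedule(ScheduleConfig())  # N=20, used for training
sampler = build_schedule(ScheduleConfig(n_steps=4))  # used for restoration

print("20-step training schedule (beta_t, alpha_t, noise level):")
for t in (1, 5, 10, 15, 20):
    print(
        f"  t={t:>2d}  beta={train.betas[t]:.6f}  "
        f"alpha={train.alphas[t]:.6f}  sqrt(beta)={noise_level(train, t):.4f}"
    )

print("\n4-step sampler schedule (same endpoints, same growth rate):")
print("  betas:", np.round(sampler.betas[1:], 6))

print("\nEffect of the growth exponent p at mid-chain (t=10 of 20):")
for p in (0.3, 1.0, 3.0):
    s = build_schedule(ScheduleConfig(p=p))
    print(f"  p={p:<4}: beta_10 = {s.betas[10]:.4f}")
print("Smaller p pushes beta up earlier: more noise in the early steps.")
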