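"""Generate a synthetic emotion-intensity dataset and inspect its structure.

Builds 200 clips of 74-channel feature sequences whose temporal dynamics
carry a 6-dimensional emotion-intensity label, then prints the emotion
frequency skew and basic shape facts.
"""

import numpy as np

from emossl import GeneratorConfig, generate, split, standardize
from emossl.synthetic import emotion_frequencies

cfg = GeneratorConfig(n_clips=200, length_range=(60, 120), seed=1, signal_strength=2.0)
ds = generate(cfg)
split(ds, fraction=0.8, seed=1)
ds, stats = standardize(ds)

lengths = [c.n_timesteps for c in ds.clips]
print(f"{len(ds)} clips, {len(ds.subset('train'))} train / {len(ds.subset('validation'))} validation")
print(f"clip lengths: min {min(lengths)}, max {max(lengths)}, features per timestep: {ds.clips[0].values.shape[1]}")
print(f"standardized value range: [{min(c.values.min() for c in ds.clips):.2f}, "
      f"{max(c.values.max() for c in ds.clips):.2f}]  (mask sentinel -30 is far outside)")

print("\nfraction of clips where each emotion is present (intensity rounds to >= 1):")
for emotion, freq in emotion_frequencies(ds).items():
    print(f"  {emotion:<10s} {freq:.2f}")
print("\nHappiness is the most common emotion; surprise and fear are rare —")
print("the same skew seen in large conversational emotion corpora.")
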