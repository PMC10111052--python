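"""Phase-locking network of one epoch and its graph statistics.

Two of the five channels share a common oscillatory source, so they phase
lock; the network statistics summarise that topology per channel.
"""

import numpy as np

from preictal import graph_statistics, plv_matrix

fs, n = 256.0, 1280
t = np.arange(n) / fs
rng = np.random.default_rng(1)
shared = np.sin(2 * np.pi * 8 * t + rng.uniform(0, 2 * np.pi))
data = np.stack([
    shared + 0.2 * rng.standard_normal(n),        # locked pair
    shared + 0.2 * rng.standard_normal(n),
    rng.standard_normal(n),                        # independent channels
    rng.standard_normal(n),
    rng.standard_normal(n),
])

net = plv_matrix(data)
print("PLV matrix (1 = rigid phase locking):")
print(np.round(net.plv, 2))

gs = graph_statistics(net, density=0.3, seed=0)
print("per-channel strength      :", np.round(gs.strength, 2))
print("per-channel synchronization:", np.round(gs.synchronization, 2))
print(f"global efficiency {gs.global_efficiency:.2f}, "
      f"path length {gs.char_path_length:.2f}, "
      f"small-world index {gs.small_world:.2f}")
print("channels 0 and 1 carry the highest strength because they share a "
      "source; the rest stay near the noise floor")
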