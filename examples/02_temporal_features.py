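"""Temporal features of one epoch: fuzzy entropy, band powers, power ratios.

A 5-s epoch yields 16 temporal features per channel: 1 fuzzy entropy
(complexity), 5 rhythm band powers (log-summed Welch PSD in delta..gamma)
and 10 spectral power ratios (all ordered band differences).
"""

import numpy as np

from preictal import BandSet, fuzzy_entropy, rpsd, spr, welch_psd
from preictal.features_temporal import SPR_PAIRS

fs = 256.0
t = np.arange(int(5 * fs)) / fs
rng = np.random.default_rng(7)
# alpha-dominant signal with broadband background
x = 20 * np.sin(2 * np.pi * 10 * t) + 5 * rng.standard_normal(len(t))

print(f"fuzzy entropy: {fuzzy_entropy(x):.4f} "
      "(0 = perfectly regular, ~2 = white noise)")

freqs, psd = welch_psd(x, fs)
bands = BandSet()
bp = rpsd(freqs, psd, bands)
for name, value in zip(bands.names, bp):
    print(f"  RPSD {name:6s} {value:7.3f}  (natural log of summed power)")

ratios = spr(bp, bands)
print("strongest power ratios (higher band minus lower band):")
for (name, hi, lo), val in sorted(zip(SPR_PAIRS, ratios),
                                  key=lambda p: -abs(p[1]))[:3]:
    print(f"  SPR {name} = {hi} - {lo} = {val:7.3f}")
print("the alpha tone dominates: alpha RPSD is highest and alpha-involving "
      "ratios are largest")
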