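"""Absolute quantification by qPCR: copy equation, standard curve, per-root
normalization.

Computes template copies from DNA concentration, fits a ten-fold dilution
standard curve, interpolates unknown Cts, and normalizes by root length.
"""

import numpy as np

from biofilmvoxel import (
    fit_standard_curve,
    interpolate_copies,
    normalize_per_root,
    template_copies,
)

# A 1 ng/ul stock of a 1000 bp amplicon (650 Da per bp):
stock = template_copies(1.0, 1000)
print(f"1 ng/ul of a 1000 bp template = {stock:.4g} copies/ul")

# Perfect doubling per cycle gives slope -1/log10(2) = -3.3219.
slope = -1 / np.log10(2)
standards = [(10**k, 30 + slope * (k - 3)) for k in (3, 4, 5, 6, 7)]
curve = fit_standard_curve(standards)
print(f"standard curve: slope = {curve.slope:.4f}, "
      f"efficiency = {100 * curve.efficiency:.1f}%, r^2 = {curve.r_squared:.4f}")

for ct in (28.0, 24.5):
    copies = interpolate_copies(curve, ct)
    per_mm = normalize_per_root(copies, root_length_mm=22.0).per_mm
    print(f"sample Ct {ct}: {copies:.4g} copies -> {per_mm:.4g} copies/mm root")
# Copies per mm of root make samples with different root sizes comparable;
# 100% efficiency means the template doubles every cycle.
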