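"""Greenwood cochlear place-frequency map.

Best frequencies follow f(x) = A (10^(a x) - k) with x the normalized
basal-apical place.  Channels are spaced uniformly in place between the
positions of ``f_min`` and ``f_max``, which is how tonotopic channel
arrays are laid out along the cochlea.  The curvature constant k = 0.85
and the guinea-pig scale A = 350 Hz are used; the slope ``a`` cancels
out of the construction.
"""

from __future__ import annotations

import numpy as np

GREENWOOD_A_HZ = 350.0
GREENWOOD_K = 0.85


def greenwood_channels(
    n_channels: int,
    f_min: float,
    f_max: float,
    A: float = GREENWOOD_A_HZ,
    k: float = GREENWOOD_K,
) -> np.ndarray:
    """Best frequencies (Hz) of ``n_channels`` places from f_min to f_max.

    Monotone increasing; endpoints map exactly to f_min and f_max.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not 0.0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    # place coordinate (up to the scale 1/a) of the two endpoint BFs
    x_lo = np.log10(f_min / A + k)
    x_hi = np.log10(f_max / A + k)
    if n_channels == 1:
        x = np.array([0.5 * (x_lo + x_hi)])
    else:
        x = np.linspace(x_lo, x_hi, n_channels)
    bf = A * (10.0**x - k)
    bf[0], bf[-1] = f_min, f_max
    return bf
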