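"""Middle-ear filter and DRNL basilar-membrane filterbank.

The middle ear is a second-order bandpass Butterworth filter (corner
frequencies per the configuration; the printed rodent values are 12.5
and 22 kHz) converting eardrum pressure to stapes velocity up to a
calibration gain.

Each basilar-membrane channel is a dual-resonance nonlinear (DRNL)
filter: the sum of a broadly tuned *linear* path (gain g, cascade of
``n_lin`` gammatone filters) and a *nonlinear* path (gammatone cascade,
memoryless broken-stick compression

    y = sign(x) * min(a |x|, b |x|^c),

gammatone cascade again).  At low levels the nonlinear path dominates
and the response is linear in the input; above the compression knee it
grows as the c-th power (c ~ 0.25), and at the highest levels the
linear path takes over.  Gammatone stages are implemented as cascades
of impulse-invariant complex one-pole sections, unit-gain at the
channel's center frequency.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def middle_ear_filter(
    pressure: np.ndarray,
    fs_hz: float,
    f_lo_hz: float = 12.5e3,
    f_hi_hz: float = 22e3,
    order: int = 2,
    gain: float = 1.0,
) -> np.ndarray:
    """Stapes velocity (model units) from eardrum pressure (Pa)."""
    nyq = fs_hz / 2.0
    if f_hi_hz >= nyq:
        raise ValueError(
            f"sampling rate {fs_hz} Hz too coarse for the {f_hi_hz} Hz "
            "corner (aliasing)"
        )
    sos = signal.butter(
        order, [f_lo_hz / nyq, f_hi_hz / nyq], btype="bandpass", output="sos"
    )
    return gain * signal.sosfilt(sos, np.asarray(pressure, dtype=float))


def gammatone_cascade(
    x: np.ndarray, fs_hz: float, cf_hz: float, bw_hz: float, order: int
) -> np.ndarray:
    """Apply ``order`` unit-peak-gain gammatone stages centered at cf."""
    if order < 1:
        return np.asarray(x, dtype=float)
    dt = 1.0 / fs_hz
    pole = np.exp((-2.0 * np.pi * bw_hz + 2.0j * np.pi * cf_hz) * dt)
    # per-stage gain so |H(cf)| = 1
    w = 2.0 * np.pi * cf_hz * dt
    g = abs(1.0 - pole * np.exp(-1.0j * w))
    y = np.asarray(x, dtype=complex)
    b = np.array([g])
    a = np.array([1.0, -pole])
    for _ in range(order):
        y = signal.lfilter(b, a, y)
    return 2.0 * y.real


def broken_stick(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Memoryless compressive nonlinearity of the DRNL nonlinear path."""
    ax = np.abs(x)
    return np.sign(x) * np.minimum(a * ax, b * np.power(ax, c, where=ax > 0,
                                                        out=np.zeros_like(ax)))


def drnl_channel(
    stapes: np.ndarray,
    fs_hz: float,
    bf_hz: float,
    n_lin: int,
    lin_gain: float,
    lin_bw_factor: float,
    nl_order: int,
    nl_a: float,
    nl_b: float,
    nl_c: float,
    bw_hz: float,
) -> np.ndarray:
    """BM velocity of one DRNL channel driven by stapes velocity.

    ``n_lin`` is the linear-path gammatone cascade length (a fiber-type
    property here: broad single-filter tuning for high-threshold
    fibers, sharper triple cascade otherwise).
    """
    lin = lin_gain * gammatone_cascade(
        stapes, fs_hz, bf_hz, lin_bw_factor * bw_hz, n_lin
    )
    nl = gammatone_cascade(stapes, fs_hz, bf_hz, bw_hz, nl_order)
    nl = broken_stick(nl, nl_a, nl_b, nl_c)
    nl = gammatone_cascade(nl, fs_hz, bf_hz, bw_hz, nl_order)
    return lin + nl
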