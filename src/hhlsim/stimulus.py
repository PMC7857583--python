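"""Sound stimulus specification.

A pure tone is described by its frequency, level re 20 uPa (dB SPL),
duration and placement inside the simulation window.  The simulation
window is ``total_sim_time`` long; the tone starts at ``onset_time`` and
everything (release rates, spikes, CAPs) shares the same uniform grid
with step ``sample_interval``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

P_REF_PA = 20e-6  # reference RMS pressure for dB SPL


@dataclass(frozen=True)
class SoundStimulus:
    """A pure-tone stimulus at the eardrum.

    Parameters
    ----------
    frequency : float
        Tone frequency in Hz.
    level : float
        Sound pressure level in dB SPL (re 20 uPa RMS).
    duration : float
        Tone duration in ms.
    sample_interval : float
        Simulation step in ms (default 0.005 ms = 5 us).
    onset_time : float
        Time of tone onset within the simulation window, ms.
    total_sim_time : float
        Total length of the simulated window, ms.
    ramp : float
        Raised-cosine on/off ramp duration in ms (0 = rectangular gate).
    """

    frequency: float
    level: float
    duration: float = 5.0
    sample_interval: float = 0.005
    onset_time: float = 0.0
    total_sim_time: float = field(default=0.0)

    ramp: float = 0.0

    def __post_init__(self):
        if self.frequency <= 0:
            raise ValueError("stimulus frequency must be positive")
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not 0.0 <= self.level <= 80.0:
            warnings.warn(
                f"sound level {self.level} dB SPL outside the validated "
                "0-80 dB range",
                stacklevel=2,
            )
        total = self.total_sim_time
        if total == 0.0:
            # default: tone plus a 5 ms tail for the CAP to play out
            total = self.onset_time + self.duration + 5.0
            object.__setattr__(self, "total_sim_time", total)
        if total < self.onset_time + self.duration:
            raise ValueError("total_sim_time must cover onset_time + duration")
        # middle-ear / basilar-membrane filters need a sane sampling rate
        if self.sample_interval > 0.25 / self.frequency * 1e3:
            raise ValueError(
                "sample_interval too coarse: need >= 4 samples per stimulus "
                "cycle"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.total_sim_time / self.sample_interval)) + 1

    @property
    def times(self) -> np.ndarray:
        """Uniform time grid in ms."""
        return np.arange(self.n_samples) * self.sample_interval

    @property
    def pressure_pa(self) -> np.ndarray:
        """Instantaneous eardrum pressure in Pa on the time grid."""
        t = self.times
        amp = np.sqrt(2.0) * P_REF_PA * 10.0 ** (self.level / 20.0)
        phase = 2.0 * np.pi * self.frequency * (t - self.onset_time) * 1e-3
        p = amp * np.sin(phase)
        gate = np.zeros_like(t)
        on = (t >= self.onset_time) & (t <= self.onset_time + self.duration)
        gate[on] = 1.0
        if self.ramp > 0.0:
            tr = (t - self.onset_time) / self.ramp
            rise = (t >= self.onset_time) & (tr < 1.0)
            gate[rise] = 0.5 - 0.5 * np.cos(np.pi * tr[rise])
            tf = (self.onset_time + self.duration - t) / self.ramp
            fall = on & (tf < 1.0)
            gate[fall] = np.minimum(gate[fall], 0.5 - 0.5 * np.cos(np.pi * tf[fall]))
        return p * gate
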