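"""Synthetic 1-D signals for exercising the pattern statistics.

Closed-form spatial/temporal test signals -- pure sinusoids, square waves,
Gaussian white noise and a sinusoid-plus-noise mixture -- so the spectral
and switching statistics can be validated independently of the simulator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["generate_signal", "white_noise_batch"]


def generate_signal(kind: str, length: int, period: float = 4.0,
                    amplitude: float = 1.0, noise_sd: float = 1.0,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    """Deterministic-given-seed synthetic signal of a named kind.

    ``sine``: ``A sin(2 pi x / period)``.  ``square``: ``+A`` for the
    first half of each period, ``-A`` for the second.  ``white_noise``:
    i.i.d. N(0, noise_sd^2).  ``mixed``: sine plus white noise.
    """
    x = np.arange(length, dtype=float)
    if kind == "sine":
        return amplitude * np.sin(2.0 * np.pi * x / period)
    if kind == "square":
        phase = np.mod(x, period) / period
        return np.where(phase < 0.5, amplitude, -amplitude)
    if rng is None:
        raise ValueError(f"kind {kind!r} needs an rng")
    if kind == "white_noise":
        return rng.normal(0.0, noise_sd, size=length)
    if kind == "mixed":
        return (amplitude * np.sin(2.0 * np.pi * x / period)
                + rng.normal(0.0, noise_sd, size=length))
    raise ValueError(f"unknown signal kind {kind!r}")


def white_noise_batch(n_signals: int, length: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Batch of Gaussian white-noise signals, shape (n_signals, length)."""
    return rng.standard_normal((n_signals, length))
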