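"""Spoiled multi-echo GRE signal model and Rician magnitude formation.

The complex signal of an RF-spoiled GRE sequence at echo time TE_n is

    s(TE_n) = M0 * E(alpha, TR, T1) * exp(-TE_n / T2*)
                 * exp(i (phi0 + 2 pi df TE_n)) + eps,

where ``E`` is the steady-state (Ernst) amplitude factor

    E = sin(alpha) (1 - exp(-TR/T1)) / (1 - cos(alpha) exp(-TR/T1))

and ``eps`` is circularly symmetric complex Gaussian noise with per-channel
standard deviation sigma.  Taking the modulus of the noisy complex signal
yields Rician-distributed magnitudes; the phase terms (phi0, off-resonance
df) drop out of the modulus, which is what justifies magnitude-only
mono-exponential T2* fitting.

Bipolar readouts can additionally suffer a parity-dependent amplitude
modulation (e.g. from the receiver frequency response): odd- and
even-parity echoes are scaled by slightly different factors.  Only the
ratio g_odd / g_even is identifiable from magnitude data -- a common scale
is absorbed into M0 -- so :class:`ParityModulation` is conventionally kept
at geometric mean one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocol import PARITY_ODD, EchoTrain


@dataclass(frozen=True)
class TissueParams:
    """Per-region ground truth: spin density M0 (a.u.), T1 and T2* (ms),
    initial phase phi0 (rad) and off-resonance delta_f (kHz)."""

    m0: float
    t1: float
    t2_star: float
    phi0: float = 0.0
    delta_f: float = 0.0

    def __post_init__(self) -> None:
        if self.m0 < 0:
            raise ValueError("m0 must be >= 0")
        if self.t1 <= 0 or self.t2_star <= 0:
            raise ValueError("t1 and t2_star must be > 0")


@dataclass(frozen=True)
class AcquisitionParams:
    """Flip angle alpha (degrees), repetition time TR (ms) and complex-noise
    standard deviation sigma per channel (a.u.)."""

    alpha: float
    tr: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 90:
            raise ValueError("alpha must lie in (0, 90] degrees")
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class ParityModulation:
    """Multiplicative amplitude factors on odd-/even-parity echoes."""

    g_odd: float = 1.0
    g_even: float = 1.0

    def __post_init__(self) -> None:
        if not (np.all(np.asarray(self.g_odd) > 0) and np.all(np.asarray(self.g_even) > 0)):
            raise ValueError("modulation factors must be > 0")

    @property
    def ratio(self):
        """The identifiable quantity g_odd / g_even."""
        return self.g_odd / self.g_even

    def normalized(self) -> "ParityModulation":
        """Rescale to geometric mean one (the identifiable convention)."""
        gm = np.sqrt(np.asarray(self.g_odd) * np.asarray(self.g_even))
        return ParityModulation(self.g_odd / gm, self.g_even / gm)

    @classmethod
    def from_ratio(cls, ratio: float) -> "ParityModulation":
        """Geometric-mean-one modulation with the given odd/even ratio."""
        r = math.sqrt(ratio)
        return cls(g_odd=r, g_even=1.0 / r)


def steady_state_factor(alpha: float, tr: float, t1: float) -> float:
    """Steady-state amplitude of a spoiled GRE sequence, in [0, 1].

    Maximised over alpha at the Ernst angle arccos(exp(-TR/T1)).
    """
    if tr <= 0 or t1 <= 0:
        raise ValueError("tr and t1 must be > 0")
    a = math.radians(alpha)
    e1 = math.exp(-tr / t1)
    return math.sin(a) * (1.0 - e1) / (1.0 - math.cos(a) * e1)


def ernst_angle(tr: float, t1: float) -> float:
    """Flip angle (degrees) maximising the steady-state amplitude."""
    return math.degrees(math.acos(math.exp(-tr / t1)))


def noiseless_signal(
    tissue: TissueParams, acq: AcquisitionParams, train: EchoTrain
) -> np.ndarray:
    """Complex signal series over the echo train (no noise, no modulation)."""
    te = train.te
    amp = tissue.m0 * steady_state_factor(acq.alpha, acq.tr, tissue.t1)
    decay = np.exp(-te / tissue.t2_star)
    phase = tissue.phi0 + 2.0 * np.pi * tissue.delta_f * te
    return amp * decay * np.exp(1j * phase)


def apply_parity_modulation(
    series: np.ndarray, parity: np.ndarray, mod: ParityModulation
) -> np.ndarray:
    """Scale odd-parity echoes by g_odd and even-parity echoes by g_even.

    ``series`` may be a single echo series or a stack with the echo axis
    last.  On a constant-parity (monopolar) train this is a uniform scale
    that an amplitude fit absorbs, leaving T2* untouched.
    """
    series = np.asarray(series)
    parity = np.asarray(parity)
    if series.shape[-1] != parity.size:
        raise ValueError("series echo axis and parity must have equal length")
    factors = np.where(parity == PARITY_ODD, mod.g_odd, mod.g_even)
    return series * factors


def to_rician_magnitude(
    series: np.ndarray, sigma: float, rng=None
) -> np.ndarray:
    """Add complex Gaussian noise of std ``sigma`` per channel and take the
    modulus.  ``rng`` is an integer seed or a ``numpy.random.Generator``;
    ``sigma = 0`` returns the exact modulus."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    series = np.asarray(series, dtype=complex)
    if sigma == 0:
        return np.abs(series)
    rng = np.random.default_rng(rng)
    noise = rng.normal(0.0, sigma, series.shape) + 1j * rng.normal(
        0.0, sigma, series.shape
    )
    return np.abs(series + noise)
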