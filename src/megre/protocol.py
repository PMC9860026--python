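"""Acquisition timing for multi-echo gradient-echo (GRE) readouts.

A multi-echo GRE sequence samples the T2* decay curve at a train of echo
times.  With *monopolar* readouts every echo is acquired under the same
readout-gradient polarity and a fly-back gradient is inserted between
echoes; with *bipolar* readouts the polarity alternates and no fly-back is
needed, which shortens the echo spacing and roughly doubles the number of
echoes per unit time.  The echo times follow from three building blocks:
the preparation time before the first acquisition window (``t_prep``), the
acquisition window itself (``t_acq``, set by the number of readout samples
and the receiver bandwidth) and the gradient ramp time (``t_ramp``)::

    monopolar: TE_n = t_prep + (2n - 1)(t_acq/2 + t_ramp) + (n - 1) t_fb
    bipolar:   TE_n = t_prep + (2n - 1)(t_acq/2 + t_ramp)

All times are milliseconds; bandwidths are Hz.  Raising the receiver
bandwidth shortens ``t_acq`` (and hence the echo spacing) but raises the
image-noise standard deviation as sqrt(BW) -- see :func:`noise_sigma`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

MONOPOLAR = "monopolar"
BIPOLAR = "bipolar"
_SCHEMES = (MONOPOLAR, BIPOLAR)

#: Parity label given to odd-numbered echoes (1st, 3rd, ...).
PARITY_ODD = 0
#: Parity label given to even-numbered echoes under a bipolar readout.
PARITY_EVEN = 1


class ProtocolError(ValueError):
    """Printed protocol numbers cannot be realised by any gradient timing."""


def _check_scheme(scheme: str) -> None:
    if scheme not in _SCHEMES:
        raise ValueError(f"polarity scheme must be one of {_SCHEMES}, got {scheme!r}")


@dataclass(frozen=True)
class GradientTiming:
    """Gradient timing blocks that determine the echo-time schedule.

    Parameters
    ----------
    t_prep:
        Time before the first acquisition window opens (RF pulse,
        slice-selection, phase-encoding and readout dephasing), ms.
    t_ramp:
        Gradient ramp-up/ramp-down duration, ms.
    t_fb:
        Fly-back gradient duration, ms.  Only monopolar trains use it;
        ``t_fb = 0`` makes the monopolar spacing degenerate to bipolar.
    raster:
        Time granularity used when rounding the acquisition window, ms.
    """

    t_prep: float
    t_ramp: float
    t_fb: float = 0.0
    raster: float = 0.01

    def __post_init__(self) -> None:
        for name in ("t_prep", "t_ramp", "t_fb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.raster <= 0:
            raise ValueError("raster must be > 0")


@dataclass(frozen=True)
class ReadoutConfig:
    """Readout-train configuration of one acquisition protocol."""

    polarity_scheme: str
    n_x: int
    bw_per_px: float
    matrix_x: int
    te_max: float

    def __post_init__(self) -> None:
        _check_scheme(self.polarity_scheme)
        if self.n_x < 1:
            raise ValueError("n_x must be >= 1")
        if self.bw_per_px <= 0:
            raise ValueError("bw_per_px must be > 0")
        if self.matrix_x < 1:
            raise ValueError("matrix_x must be >= 1")

    @property
    def bw_total(self) -> float:
        """Total receiver bandwidth BW = bw_per_px * matrix_x (Hz)."""
        return self.bw_per_px * self.matrix_x


@dataclass(frozen=True)
class EchoTrain:
    """An ordered echo-time schedule with per-echo readout polarity.

    ``parity`` holds :data:`PARITY_ODD` / :data:`PARITY_EVEN` labels; a
    monopolar train has constant parity, a bipolar train alternates.
    """

    te: np.ndarray
    parity: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        parity = np.asarray(self.parity, dtype=np.int8)
        if te.ndim != 1 or te.size < 1:
            raise ValueError("te must be a non-empty 1-D array")
        if te.size != parity.size:
            raise ValueError("te and parity must have equal length")
        if te.size > 1 and not np.all(np.diff(te) > 0):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "te", te)
        object.__setattr__(self, "parity", parity)

    @property
    def n_e(self) -> int:
        return int(self.te.size)

    @property
    def delta_te(self) -> float | None:
        """Uniform echo spacing in ms, or ``None`` for a non-uniform train."""
        if self.n_e < 2:
            return None
        d = np.diff(self.te)
        if np.allclose(d, d[0], rtol=0.0, atol=1e-9):
            return float(d[0])
        return None

    @property
    def is_alternating(self) -> bool:
        """True when consecutive echoes carry opposite readout polarity."""
        return self.n_e >= 2 and bool(np.all(np.diff(self.parity) != 0))

    def subset(self, index) -> "EchoTrain":
        """Return the sub-train at the given (sorted) echo indices."""
        return EchoTrain(self.te[index], self.parity[index])


def acquisition_time(n_x: int, bw_total: float, raster: float = 0.01) -> float:
    """Acquisition-window duration t_acq = n_x / BW, ceiled to the raster.

    Parameters are the readout sample count, the total receiver bandwidth
    in Hz, and the timing raster in ms.  Returns milliseconds.
    """
    if n_x < 1:
        raise ValueError("n_x must be >= 1")
    if bw_total <= 0 or raster <= 0:
        raise ValueError("bw_total and raster must be > 0")
    t_ms = 1e3 * n_x / bw_total
    # tiny tolerance so exact raster multiples do not ceil one step up
    return math.ceil(t_ms / raster - 1e-9) * raster


def te_schedule(
    timing: GradientTiming, t_acq: float, scheme: str, n_e: int
) -> EchoTrain:
    """Build the echo-time schedule for one readout polarity scheme.

    Both schemes share TE_1 = t_prep + t_acq/2 + t_ramp; the monopolar
    spacing adds the fly-back duration per echo.
    """
    _check_scheme(scheme)
    if n_e < 1:
        raise ValueError("n_e must be >= 1")
    if t_acq <= 0:
        raise ValueError("t_acq must be > 0")
    n = np.arange(1, n_e + 1)
    te = timing.t_prep + (2 * n - 1) * (t_acq / 2.0 + timing.t_ramp)
    if scheme == MONOPOLAR:
        te = te + (n - 1) * timing.t_fb
        parity = np.full(n_e, PARITY_ODD, dtype=np.int8)
    else:
        parity = ((n - 1) % 2).astype(np.int8)
    return EchoTrain(te, parity)


def count_echoes(te_1: float, delta_te: float, te_max: float) -> int:
    """Largest N with te_1 + (N-1) * delta_te <= te_max (boundary inclusive).

    Returns 0 when ``te_max`` lies below the first echo.
    """
    if delta_te <= 0:
        raise ValueError("delta_te must be > 0")
    if te_max < te_1 - 1e-9:
        return 0
    return int(math.floor((te_max - te_1) / delta_te + 1e-9)) + 1


def timing_from_protocol(
    te_1: float,
    delta_te_mono: float,
    delta_te_bip: float,
    t_acq: float,
    raster: float = 0.01,
) -> GradientTiming:
    """Invert printed protocol numbers (TE_1, both echo spacings, t_acq)
    into one consistent gradient timing.

    The decomposition is::

        t_ramp = (delta_te_bip - t_acq) / 2
        t_fb   = delta_te_mono - delta_te_bip
        t_prep = te_1 - t_acq/2 - t_ramp

    and round-trips through :func:`te_schedule` on (TE_1, both spacings).
    """
    if not (delta_te_mono >= delta_te_bip >= t_acq):
        raise ProtocolError(
            "inconsistent protocol: need delta_te_mono >= delta_te_bip >= t_acq"
        )
    t_ramp = (delta_te_bip - t_acq) / 2.0
    t_fb = delta_te_mono - delta_te_bip
    t_prep = te_1 - t_acq / 2.0 - t_ramp
    if t_prep < 0:
        raise ProtocolError("inconsistent protocol: derived t_prep is negative")
    return GradientTiming(t_prep=t_prep, t_ramp=t_ramp, t_fb=t_fb, raster=raster)


def noise_sigma(sigma_0: float, bw: float, bw_0: float) -> float:
    """Bandwidth scaling of the complex-noise standard deviation.

    sigma = sigma_0 * sqrt(BW / BW_0): doubling the total receiver
    bandwidth halves the acquisition window but raises the noise floor by
    sqrt(2).
    """
    if sigma_0 <= 0 or bw <= 0 or bw_0 <= 0:
        raise ValueError("sigma_0, bw and bw_0 must be > 0")
    return sigma_0 * math.sqrt(bw / bw_0)


# ---------------------------------------------------------------------------
# Shipped protocol presets
# ---------------------------------------------------------------------------

def _load_preset_file(path: str | Path | None = None) -> dict:
    if path is None:
        text = resources.files("megre.data").joinpath("protocols.yaml").read_text()
    else:
        text = Path(path).read_text()
    return yaml.safe_load(text)


_PRESETS: dict | None = None


def preset_names() -> list[str]:
    """Names of the shipped acquisition-protocol presets."""
    return sorted(_presets())


def _presets() -> dict:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_preset_file()
    return _PRESETS


def load_protocol(name_or_path: str) -> dict:
    """Load a protocol description by preset name or YAML file path.

    The dialect carries ``scheme, te1_ms, delta_te_ms, te_max_ms,
    bw_per_px_hz, matrix, n_x``.
    """
    presets = _presets()
    if name_or_path in presets:
        return dict(presets[name_or_path])
    path = Path(name_or_path)
    if path.exists():
        cfg = yaml.safe_load(path.read_text())
        if len(cfg) == 1 and isinstance(next(iter(cfg.values())), dict):
            cfg = next(iter(cfg.values()))
        return dict(cfg)
    raise KeyError(
        f"unknown protocol {name_or_path!r}; presets: {preset_names()}"
    )


def train_from_params(
    te_1: float,
    delta_te: float,
    scheme: str,
    te_max: float | None = None,
    n_e: int | None = None,
) -> EchoTrain:
    """Uniform echo train straight from (TE_1, delta_te).

    Give either ``te_max`` (echo count by the inclusive boundary rule) or
    ``n_e`` explicitly.
    """
    _check_scheme(scheme)
    if (te_max is None) == (n_e is None):
        raise ValueError("give exactly one of te_max or n_e")
    if n_e is None:
        n_e = count_echoes(te_1, delta_te, te_max)
    if n_e < 1:
        raise ValueError("echo train is empty for the requested TE range")
    te = te_1 + np.arange(n_e) * delta_te
    if scheme == MONOPOLAR:
        parity = np.full(n_e, PARITY_ODD, dtype=np.int8)
    else:
        parity = (np.arange(n_e) % 2).astype(np.int8)
    return EchoTrain(te, parity)


def protocol_train(
    name_or_cfg: str | dict,
    scheme: str | None = None,
    te_max: float | None = None,
) -> EchoTrain:
    """Echo train for a shipped preset (or loaded protocol dict)."""
    cfg = load_protocol(name_or_cfg) if isinstance(name_or_cfg, str) else dict(name_or_cfg)
    scheme = scheme or cfg["scheme"]
    te_max = te_max if te_max is not None else cfg["te_max_ms"]
    return train_from_params(cfg["te1_ms"], cfg["delta_te_ms"], scheme, te_max=te_max)
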