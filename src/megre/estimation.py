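"""Voxelwise T2* estimation from multi-echo magnitude data.

The decay model is mono-exponential, nu_n = A exp(-TE_n / T2*), where A
bundles spin density and the steady-state amplitude factor (the only
amplitude identifiable from magnitude data).  Magnitudes are Rician with
known noise level sigma, so the default estimator maximises the Rician
log-likelihood

    log p(m | nu, sigma) = log(m / sigma^2) - (m^2 + nu^2) / (2 sigma^2)
                           + log I0(m nu / sigma^2)

summed over echoes.  At high SNR this degenerates to ordinary least
squares; at low SNR the Rician term removes the noise-floor bias that
makes naive magnitude fits overestimate T2*.  sigma is estimated once
from the noise-only background corners (Rayleigh statistics) and treated
as known during fitting, leaving two free parameters (A, T2*).

Bipolar echo trains may carry parity-dependent amplitude modulation;
:func:`correct_amplitude_modulation` removes it by iteratively fitting,
synthesising the fitted decay, and rescaling odd/even echoes by the
median measured/synthesised ratio per parity (geometric-mean-one
normalised, since the common scale is absorbed by A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .phantom_sim import SimulatedSeries
from .protocol import PARITY_EVEN, PARITY_ODD, EchoTrain
from .signal_model import ParityModulation

_SQRT_HALF_PI = math.sqrt(math.pi / 2.0)


class AMNotApplicableError(ValueError):
    """Amplitude-modulation correction needs an alternating-parity train."""


@dataclass(frozen=True)
class NoiseEstimate:
    """Complex-noise standard deviation recovered from background voxels."""

    sigma: float
    n_voxels: int
    method: str

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class FitResult:
    """Per-voxel decay fit: amplitude A (a.u.), T2* (ms), diagnostics."""

    amplitude: float
    t2_star: float
    converged: bool
    n_iter: int
    objective: float


@dataclass
class FitOptions:
    """Tunables of the voxelwise fit.

    ``likelihood`` is ``"rician"`` or ``"gaussian"`` (plain least squares);
    with ``sigma = 0`` the Gaussian branch is used regardless.  The
    log-linear initialiser uses echoes above ``init_floor_snr * sigma``.
    """

    likelihood: str = "rician"
    t2_bounds: tuple[float, float] = (1.0, 1000.0)
    init_floor_snr: float = 2.0
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.likelihood not in ("rician", "gaussian"):
            raise ValueError("likelihood must be 'rician' or 'gaussian'")
        lo, hi = self.t2_bounds
        if not 0 < lo < hi:
            raise ValueError("t2_bounds must satisfy 0 < lo < hi")


@dataclass
class AMCorrectionResult:
    """Outcome of the iterative amplitude-modulation correction."""

    modulation: ParityModulation
    corrected: np.ndarray
    fit: object
    n_iter: int
    converged: bool


# ---------------------------------------------------------------------------
# Noise estimation
# ---------------------------------------------------------------------------

def estimate_noise_background(
    stack, corner_rois=None, method: str = "rayleigh_second_moment"
) -> NoiseEstimate:
    """Recover the complex-Gaussian sigma from noise-only magnitudes.

    Background magnitudes are Rayleigh(sigma): the second moment gives
    sigma = sqrt(mean(M^2) / 2) (default) and the mean gives
    sigma = mean(M) / sqrt(pi/2).  ``corner_rois`` is one boolean mask or
    a list of masks over the image plane; with a :class:`SimulatedSeries`
    all echoes of the masked voxels are pooled.
    """
    data = stack.data if isinstance(stack, SimulatedSeries) else np.asarray(stack)
    if corner_rois is None:
        values = data.reshape(-1)
        n_vox = values.size // (data.shape[-1] if data.ndim > 1 else 1)
    else:
        masks = corner_rois if isinstance(corner_rois, (list, tuple)) else [corner_rois]
        mask = np.zeros(data.shape[:-1] if data.ndim > 1 else data.shape, dtype=bool)
        for m in masks:
            mask |= np.asarray(m, dtype=bool)
        n_vox = int(mask.sum())
        if n_vox == 0:
            raise ValueError("empty background masks")
        values = data[mask].reshape(-1) if data.ndim > 1 else data[mask]
    if values.size == 0:
        raise ValueError("no background voxels")
    if method == "rayleigh_second_moment":
        sigma = math.sqrt(float(np.mean(values**2)) / 2.0)
    elif method == "rayleigh_mean":
        sigma = float(np.mean(values)) / _SQRT_HALF_PI
    else:
        raise ValueError(f"unknown method {method!r}")
    return NoiseEstimate(sigma=sigma, n_voxels=n_vox, method=method)


# ---------------------------------------------------------------------------
# Single-series fit
# ---------------------------------------------------------------------------

def _init_loglinear(te, m, sigma, t2_bounds, floor_snr):
    """Log-linear (ordinary regression) starting point for (A, T2*)."""
    lo, hi = t2_bounds
    floor = max(floor_snr * sigma, 1e-12)
    sel = m > floor
    if sel.sum() >= 3:
        slope, intercept = np.polyfit(te[sel], np.log(m[sel]), 1)
        if slope < -1e-12:
            t2 = -1.0 / slope
            a = math.exp(min(intercept, 700.0))
        else:  # non-decaying start: fall back to a mid-range guess
            t2 = 0.5 * (te[-1] - te[0])
            a = float(np.max(m))
    else:
        t2 = 0.5 * (te[-1] - te[0])
        a = float(np.max(m))
    t2 = min(max(t2, lo), hi)
    return max(a, 1e-12), t2


def _rician_nll_grad(params, te, m, inv_s2, log_m_term):
    a, t2 = params
    decay = np.exp(-te / t2)
    nu = a * decay
    z = m * nu * inv_s2
    i0e = special.i0e(z)
    r = special.i1e(z) / i0e
    nll = float(
        np.sum(0.5 * (m**2 + nu**2) * inv_s2 - z - np.log(i0e)) - log_m_term
    )
    dnu = (nu - m * r) * inv_s2  # d nll / d nu per echo
    da = float(np.sum(dnu * decay))
    dt2 = float(np.sum(dnu * nu * te) / t2**2)
    return nll, np.array([da, dt2])


def _gaussian_nll_grad(params, te, m, inv_s2, _unused):
    a, t2 = params
    decay = np.exp(-te / t2)
    nu = a * decay
    resid = nu - m
    nll = 0.5 * float(np.sum(resid**2)) * inv_s2
    da = float(np.sum(resid * decay)) * inv_s2
    dt2 = float(np.sum(resid * nu * te)) * inv_s2 / t2**2
    return nll, np.array([da, dt2])


def fit_t2star_rician(
    train: EchoTrain,
    magnitudes: np.ndarray,
    sigma: float,
    options: FitOptions | None = None,
) -> FitResult:
    """Maximum-likelihood mono-exponential fit of one magnitude series.

    ``sigma`` is the known complex-noise standard deviation; ``sigma = 0``
    (or Gaussian options) selects plain least squares.  Requires at least
    three echoes.  Non-convergence is flagged on the result, not raised.
    """
    opts = options or FitOptions()
    te = train.te
    m = np.asarray(magnitudes, dtype=float)
    if m.shape != te.shape:
        raise ValueError("magnitudes must match the echo train length")
    if train.n_e < 3:
        raise ValueError("need at least 3 echoes to fit (A, T2*)")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")

    use_gaussian = opts.likelihood == "gaussian" or sigma == 0
    inv_s2 = 1.0 / sigma**2 if sigma > 0 else 1.0
    if use_gaussian:
        fun = _gaussian_nll_grad
        extra = None
    else:
        fun = _rician_nll_grad
        # constant data term of the full Rician NLL (kept so `objective`
        # is the true negative log-likelihood)
        extra = float(np.sum(np.log(np.maximum(m, 1e-300) * inv_s2)))

    a0, t20 = _init_loglinear(te, m, sigma, opts.t2_bounds, opts.init_floor_snr)
    lo, hi = opts.t2_bounds

    def run(x0):
        return optimize.minimize(
            fun,
            x0=np.asarray(x0),
            args=(te, m, inv_s2, extra),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, None), (lo, hi)],
            options={"maxiter": opts.max_iter},
        )

    res = run([a0, t20])
    # Poor starting points can strand low-SNR fits at the T2* bounds even
    # when an interior optimum exists; retry from decay-scale guesses and
    # keep the best likelihood.
    if not res.success or not lo * (1 + 1e-9) < res.x[1] < hi * (1 - 1e-9):
        span = te[-1] - te[0]
        for t2_try in (0.25 * span, span):
            t2_try = min(max(t2_try, lo), hi)
            a_try = max(float(m[0]) * math.exp(te[0] / t2_try), 1e-12)
            alt = run([a_try, t2_try])
            if alt.fun < res.fun:
                res = alt
    a_hat, t2_hat = res.x
    at_bound = t2_hat <= lo * (1 + 1e-9) or t2_hat >= hi * (1 - 1e-9)
    return FitResult(
        amplitude=float(a_hat),
        t2_star=float(t2_hat),
        converged=bool(res.success) and not at_bound,
        n_iter=int(res.nit),
        objective=float(res.fun),
    )


# ---------------------------------------------------------------------------
# Map-level fit
# ---------------------------------------------------------------------------

def fit_t2star_map(
    stack,
    train: EchoTrain | None = None,
    sigma: float | None = None,
    options: FitOptions | None = None,
    mask: np.ndarray | None = None,
):
    """Apply the voxelwise fit over a foreground mask.

    ``stack`` is a :class:`~megre.phantom_sim.SimulatedSeries` (train and
    sigma then default from it) or a (rows, cols, echoes) array.  Voxels
    outside the mask carry NaN sentinels.  Returns (t2_star map,
    amplitude map, diagnostics dict).
    """
    if isinstance(stack, SimulatedSeries):
        data = stack.data
        train = train or stack.train
        sigma = stack.sigma_true if sigma is None else sigma
    else:
        data = np.asarray(stack, dtype=float)
        if train is None or sigma is None:
            raise ValueError("train and sigma are required with a bare array")
    if data.ndim != 3:
        raise ValueError("stack must be rows x cols x echoes")
    if mask is None:
        if sigma > 0:  # default foreground: mean magnitude above the noise floor
            mask = data.mean(axis=-1) > 5.0 * sigma
        else:
            mask = data.mean(axis=-1) > 0
    mask = np.asarray(mask, dtype=bool)
    t2_map = np.full(data.shape[:2], np.nan)
    amp_map = np.full(data.shape[:2], np.nan)
    n_conv = 0
    idx = np.nonzero(mask)
    for i, j in zip(*idx):
        fit = fit_t2star_rician(train, data[i, j], sigma, options)
        t2_map[i, j] = fit.t2_star
        amp_map[i, j] = fit.amplitude
        n_conv += fit.converged
    diagnostics = {
        "n_fit": int(mask.sum()),
        "n_converged": int(n_conv),
        "sigma": float(sigma),
    }
    return t2_map, amp_map, diagnostics


def fit_t2star_batch(
    train: EchoTrain,
    magnitudes: np.ndarray,
    sigma: float,
    options: FitOptions | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit a (n_series, n_e) batch of independent decay curves.

    Convenience wrapper used by Monte-Carlo studies; returns arrays of
    T2*, amplitude and convergence flags.
    """
    m = np.atleast_2d(np.asarray(magnitudes, dtype=float))
    t2 = np.empty(m.shape[0])
    amp = np.empty(m.shape[0])
    conv = np.empty(m.shape[0], dtype=bool)
    for k in range(m.shape[0]):
        fit = fit_t2star_rician(train, m[k], sigma, options)
        t2[k], amp[k], conv[k] = fit.t2_star, fit.amplitude, fit.converged
    return t2, amp, conv


# ---------------------------------------------------------------------------
# Amplitude-modulation correction
# ---------------------------------------------------------------------------

def correct_amplitude_modulation(
    stack,
    train: EchoTrain | None = None,
    sigma: float | None = None,
    max_iter: int = 10,
    tol: float = 1e-4,
    mode: str = "voxel",
    mask: np.ndarray | None = None,
    options: FitOptions | None = None,
) -> AMCorrectionResult:
    """Iteratively remove parity-dependent amplitude modulation.

    Each pass (1) fits (A, T2*) on all echoes, (2) synthesises the fitted
    decay, (3) takes the median measured/synthesised ratio over odd- and
    even-parity echoes (per voxel by default, pooled over the mask with
    ``mode="pooled"``), normalises the two factors to geometric mean one,
    and (4) divides them out.  Stops when max|g - 1| < ``tol`` or after
    ``max_iter`` passes.  Only applicable to alternating-parity (bipolar)
    trains with at least four echoes.
    """
    if mode not in ("voxel", "pooled"):
        raise ValueError("mode must be 'voxel' or 'pooled'")
    if isinstance(stack, SimulatedSeries):
        data = stack.data
        train = train or stack.train
        sigma = stack.sigma_true if sigma is None else sigma
    else:
        data = np.asarray(stack, dtype=float)
        if train is None or sigma is None:
            raise ValueError("train and sigma are required with a bare array")
    if not train.is_alternating:
        raise AMNotApplicableError(
            "amplitude-modulation correction needs alternating readout parity"
        )
    if train.n_e < 4:
        raise ValueError("need at least 4 echoes for parity factor estimation")

    single = data.ndim == 1
    work_shape = (1, 1, data.shape[-1]) if single else data.shape
    data3 = data.reshape(work_shape)
    if mask is None:
        if single:
            mask = np.ones((1, 1), dtype=bool)
        elif sigma > 0:
            mask = data3.mean(axis=-1) > 5.0 * sigma
        else:
            mask = data3.mean(axis=-1) > 0
    mask = np.asarray(mask, dtype=bool).reshape(work_shape[:2])
    if not np.any(mask):
        raise ValueError("empty foreground mask")

    odd = train.parity == PARITY_ODD
    even = train.parity == PARITY_EVEN
    work = data3[mask].astype(float)  # (n_vox, n_e)
    n_vox = work.shape[0]
    g_odd_tot = np.ones(n_vox)
    g_even_tot = np.ones(n_vox)
    converged = False
    it = 0
    t2 = amp = None
    for it in range(1, max_iter + 1):
        t2, amp, _ = fit_t2star_batch(train, work, sigma, options)
        nu = amp[:, None] * np.exp(-train.te[None, :] / t2[:, None])
        ratio = work / np.maximum(nu, 1e-300)
        if mode == "voxel":
            go = np.median(ratio[:, odd], axis=1)
            ge = np.median(ratio[:, even], axis=1)
        else:
            go = np.full(n_vox, np.median(ratio[:, odd]))
            ge = np.full(n_vox, np.median(ratio[:, even]))
        gm = np.sqrt(go * ge)
        go, ge = go / gm, ge / gm
        work[:, odd] /= go[:, None]
        work[:, even] /= ge[:, None]
        g_odd_tot *= go
        g_even_tot *= ge
        if max(np.abs(go - 1.0).max(), np.abs(ge - 1.0).max()) < tol:
            converged = True
            break
    # final fit on the corrected data
    t2, amp, conv = fit_t2star_batch(train, work, sigma, options)

    corrected = data3.astype(float).copy()
    corrected[mask] = work
    corrected = corrected.reshape(data.shape)
    if single:
        modulation = ParityModulation(float(g_odd_tot[0]), float(g_even_tot[0]))
        fit: object = FitResult(
            amplitude=float(amp[0]),
            t2_star=float(t2[0]),
            converged=bool(conv[0]),
            n_iter=it,
            objective=float("nan"),
        )
    else:
        if mode == "pooled":
            modulation = ParityModulation(float(g_odd_tot[0]), float(g_even_tot[0]))
        else:
            modulation = ParityModulation(g_odd_tot, g_even_tot)
        t2_map = np.full(work_shape[:2], np.nan)
        amp_map = np.full(work_shape[:2], np.nan)
        t2_map[mask] = t2
        amp_map[mask] = amp
        fit = {"t2_star": t2_map, "amplitude": amp_map, "n_converged": int(conv.sum())}
    return AMCorrectionResult(
        modulation=modulation,
        corrected=corrected,
        fit=fit,
        n_iter=it,
        converged=converged,
    )
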