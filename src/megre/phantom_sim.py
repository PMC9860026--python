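"""Digital phantom and synthetic multi-echo magnitude data.

The phantom mimics a homogeneous spherical phantom holding five flasks
whose relaxation times span the brain-tissue range at 3 T: five circular
regions with

    (T2*, T1) = (49, 671), (78, 959), (69, 878), (99, 1134), (133, 1372) ms

arranged on a ring inside a disc, with four noise-only rectangles in the
image corners (>= 300 voxels each) reserved for background noise
estimation.  Region 3 (T2* = 69 ms) is the canonical region of interest
for precision comparisons.

Simulated series follow the spoiled-GRE signal model voxelwise, optionally
with parity-dependent amplitude modulation, and magnitudes are formed from
complex Gaussian noise (Rician in signal regions, Rayleigh in the
background).  The two retrospective echo-subsampling schemes -- keep the
first n echoes (shrinks the TE range) or keep every n-th echo (stretches
the echo spacing) -- operate on stored stacks, never by re-simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .protocol import EchoTrain
from .signal_model import (
    AcquisitionParams,
    ParityModulation,
    TissueParams,
    apply_parity_modulation,
    noiseless_signal,
    to_rician_magnitude,
)

#: (T2* ms, T1 ms) per region id, matching the five-flask phantom.
DEFAULT_REGION_PARAMS: dict[int, TissueParams] = {
    1: TissueParams(m0=1.0, t1=671.0, t2_star=49.0),
    2: TissueParams(m0=1.0, t1=959.0, t2_star=78.0),
    3: TissueParams(m0=1.0, t1=878.0, t2_star=69.0),
    4: TissueParams(m0=1.0, t1=1134.0, t2_star=99.0),
    5: TissueParams(m0=1.0, t1=1372.0, t2_star=133.0),
}


@dataclass
class DigitalPhantom:
    """Label map plus per-region tissue parameters.

    Label 0 is noise-only background; every nonzero label must have an
    entry in ``regions``.
    """

    label_map: np.ndarray
    regions: dict[int, TissueParams]
    corner_size: int = 20

    def __post_init__(self) -> None:
        self.label_map = np.asarray(self.label_map)
        labels = set(np.unique(self.label_map)) - {0}
        missing = labels - set(self.regions)
        if missing:
            raise ValueError(f"labels without tissue parameters: {sorted(missing)}")

    @property
    def matrix(self) -> tuple[int, int]:
        return tuple(self.label_map.shape)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.label_map == region_id

    def corner_masks(self) -> list[np.ndarray]:
        """Four background rectangles at the image corners."""
        r, c = self.label_map.shape
        s = self.corner_size
        masks = []
        for rows in (slice(0, s), slice(r - s, r)):
            for cols in (slice(0, s), slice(c - s, c)):
                m = np.zeros_like(self.label_map, dtype=bool)
                m[rows, cols] = True
                masks.append(m)
        return masks


@dataclass
class SimulatedSeries:
    """Magnitude stack (row x column x echo) with its echo train, the true
    noise level and the seed used, so every dataset regenerates exactly."""

    data: np.ndarray
    train: EchoTrain
    sigma_true: float
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.shape[-1] != self.train.n_e:
            raise ValueError("echo axis length must equal train.n_e")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")

    @property
    def n_e(self) -> int:
        return self.train.n_e


def build_default_phantom(
    matrix: tuple[int, int] = (240, 240),
    regions: dict[int, TissueParams] | None = None,
) -> DigitalPhantom:
    """Five circular regions on a ring inside a disc, corners left empty.

    Geometry scales with the matrix: disc radius 0.40 min(matrix), region
    ring radius 0.25, region radius 0.11.  Raises when the matrix cannot
    host five regions plus four >= 300-voxel background corners.
    """
    rows, cols = matrix
    m = min(rows, cols)
    if m < 64:
        raise ValueError("matrix must be at least 64 x 64")
    corner = 20 if m >= 160 else 18  # 400 or 324 voxels per corner
    disc_r = 0.40 * m
    ring_r = 0.25 * m
    reg_r = 0.11 * m
    # the corner rectangles must stay strictly outside the disc
    centre = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    nearest_corner = math.hypot(centre[0] - (corner - 1), centre[1] - (corner - 1))
    if nearest_corner <= disc_r + 1:
        raise ValueError(
            "matrix too small to host five regions and four background corners"
        )
    rr, cc = np.mgrid[0:rows, 0:cols]
    label = np.zeros((rows, cols), dtype=np.int16)
    region_params = dict(regions or DEFAULT_REGION_PARAMS)
    angles = -np.pi / 2 + 2 * np.pi * np.arange(len(region_params)) / len(region_params)
    for (rid, _), ang in zip(sorted(region_params.items()), angles):
        cy = centre[0] + ring_r * math.sin(ang)
        cx = centre[1] + ring_r * math.cos(ang)
        mask = (rr - cy) ** 2 + (cc - cx) ** 2 <= reg_r**2
        if np.any(label[mask] != 0):
            raise ValueError("region geometry overlaps; matrix too small")
        label[mask] = rid
    return DigitalPhantom(label, region_params, corner_size=corner)


def simulate_series(
    phantom: DigitalPhantom,
    acq: AcquisitionParams,
    train: EchoTrain,
    mod: ParityModulation | None = None,
    seed: int | None = 0,
    provenance: dict | None = None,
) -> SimulatedSeries:
    """Simulate a full multi-echo magnitude stack for the phantom.

    Every voxel of a region follows the noiseless spoiled-GRE series of
    its tissue parameters (optionally parity-modulated); complex Gaussian
    noise of std ``acq.sigma`` is then added and the modulus taken.
    Background voxels carry pure Rayleigh noise.  Deterministic under a
    fixed seed.
    """
    rows, cols = phantom.matrix
    stack = np.zeros((rows, cols, train.n_e), dtype=complex)
    for rid, tissue in phantom.regions.items():
        mask = phantom.region_mask(rid)
        if not np.any(mask):
            continue
        sig = noiseless_signal(tissue, acq, train)
        if mod is not None:
            sig = apply_parity_modulation(sig, train.parity, mod)
        stack[mask] = sig
    rng = np.random.default_rng(seed)
    data = to_rician_magnitude(stack, acq.sigma, rng)
    prov = dict(provenance or {})
    prov.setdefault("alpha", acq.alpha)
    prov.setdefault("tr", acq.tr)
    return SimulatedSeries(
        data=data, train=train, sigma_true=acq.sigma, seed=seed, provenance=prov
    )


def select_first_n(series: SimulatedSeries, n: int) -> SimulatedSeries:
    """Keep the first ``n`` echoes (shrinks the TE range)."""
    if not 1 <= n <= series.n_e:
        raise ValueError(f"n must lie in [1, {series.n_e}], got {n}")
    idx = slice(0, n)
    return SimulatedSeries(
        data=series.data[..., idx],
        train=series.train.subset(idx),
        sigma_true=series.sigma_true,
        seed=series.seed,
        provenance={**series.provenance, "select_first_n": n},
    )


def select_every_nth(series: SimulatedSeries, n: int) -> SimulatedSeries:
    """Keep echoes 1, 1+n, 1+2n, ... (multiplies the echo spacing by n).

    Parity labels are carried over from the source train, so an even
    stride on a bipolar train yields a constant-parity train -- amplitude
    modulation then acts as a uniform scale, as with monopolar data.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = np.arange(0, series.n_e, n)
    return SimulatedSeries(
        data=series.data[..., idx],
        train=series.train.subset(idx),
        sigma_true=series.sigma_true,
        seed=series.seed,
        provenance={**series.provenance, "select_every_nth": n},
    )
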