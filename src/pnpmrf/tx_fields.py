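"""Synthetic multi-element transmit fields, coil modes, calibration, shimming.

Element fields come from an analytic ring-source model (decaying amplitude,
wavelength-dependent phase) that reproduces the qualitative structure of
full-wave simulations: a centre-bright circularly-polarized (CP) mode, a
gradient mode with a central null, and complementary B1+ voids between the
two at short effective wavelengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElementFieldSet",
    "DriveVector",
    "NetField",
    "mode_weights",
    "combine",
    "approx_cp_calibration",
    "mls_shim",
    "field_cv",
    "synthetic_element_fields",
    "default_illuminations",
]


@dataclass
class ElementFieldSet:
    """Per-element complex B1+ maps (uT per unit drive) on the image grid."""

    fields: np.ndarray  # (K, M, M) complex
    element_positions: np.ndarray  # (K, 2) pixel coordinates

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.fields)):
            raise ValueError("element fields must be finite everywhere")

    @property
    def n_elements(self) -> int:
        return self.fields.shape[0]


@dataclass
class DriveVector:
    """Complex per-element drive weights."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=complex)


@dataclass
class NetField:
    """Combined complex B1+ map with provenance."""

    map: np.ndarray  # (M, M) complex, uT
    provenance: str = ""


def mode_weights(K: int, n: int) -> DriveVector:
    """Orthogonal ring-coil mode ``n``: phases advance by ``n * 2pi/K``.

    Mode 1 is the CP mode; mode 2 the gradient mode.
    """
    if not 1 <= n <= K:
        raise ValueError(f"mode index {n} out of range 1..{K}")
    alpha = 2.0 * math.pi / K
    k = np.arange(K)
    return DriveVector(np.exp(1j * n * alpha * k) / math.sqrt(K))


def combine(S: ElementFieldSet, b: DriveVector) -> NetField:
    """Pointwise superposition ``S @ b``."""
    if len(b.weights) != S.n_elements:
        raise ValueError(
            f"drive length {len(b.weights)} does not match {S.n_elements} elements"
        )
    net = np.tensordot(b.weights, S.fields, axes=(0, 0))
    return NetField(net, provenance="combine")


def approx_cp_calibration(S: ElementFieldSet, centre_region: np.ndarray) -> DriveVector:
    """Align per-element phases over a central region (approximate CP mode).

    Weight ``k`` is ``exp(-i * arg(mean field of element k over the region))``;
    the approximate gradient mode is obtained by multiplying these weights by
    ``exp(i * alpha * k)`` (see :func:`derived_gradient_mode`).
    """
    if not np.any(centre_region):
        raise ValueError("centre region is empty")
    means = S.fields[:, centre_region].mean(axis=1)
    dead = np.flatnonzero(np.abs(means) < 1e-15)
    if len(dead):
        raise ValueError(
            f"degenerate calibration: element {dead[0]} has zero mean field "
            "in the centre region"
        )
    return DriveVector(np.exp(-1j * np.angle(means)) / math.sqrt(S.n_elements))


def derived_gradient_mode(cp_weights: DriveVector) -> DriveVector:
    """Approximate gradient mode: increment the CP phases by the azimuthal angle."""
    K = len(cp_weights.weights)
    alpha = 2.0 * math.pi / K
    return DriveVector(cp_weights.weights * np.exp(1j * alpha * np.arange(K)))


def mls_shim(
    S: ElementFieldSet,
    m: np.ndarray,
    mask: np.ndarray,
    n_iter: int = 50,
    seed: int | None = None,
    n_restarts: int = 1,
) -> tuple:
    """Magnitude-least-squares shim by variable exchange.

    Minimizes ``|| |S b| - m ||^2`` over the mask.  Initialized from the CP
    mode; with ``n_restarts > 1`` additional random-phase starts (seeded
    from ``seed``) are tried and the best run kept — the objective is
    non-convex, so restarts help escape local minima.  Returns
    ``(DriveVector, objective_history)``; the history of any single run is
    non-increasing.
    """
    if not np.any(mask):
        raise ValueError("mask is empty")
    m_v = np.asarray(m, dtype=float)[mask]
    if np.any(m_v <= 0):
        raise ValueError("target magnitude must be positive on the mask")
    A = S.fields[:, mask].T  # (V, K)
    K = S.n_elements

    inits = [mode_weights(K, 1).weights if seed is None else
             np.exp(1j * np.random.default_rng(seed).uniform(0, 2 * math.pi, K))
             / math.sqrt(K)]
    base = 0 if seed is None else seed
    for r in range(1, n_restarts):
        rng = np.random.default_rng(base + r)
        inits.append(np.exp(1j * rng.uniform(0, 2 * math.pi, K)) / math.sqrt(K))

    best = None
    for b in inits:
        history = []
        for _ in range(n_iter):
            phase = np.exp(1j * np.angle(A @ b))
            target = m_v * phase
            b_new, *_ = np.linalg.lstsq(A, target, rcond=None)
            obj_new = float(np.sum((np.abs(A @ b_new) - m_v) ** 2))
            if history and obj_new > history[-1]:
                break  # variable exchange is monotone; stop if numerics disagree
            b = b_new
            history.append(obj_new)
        if not history:
            history.append(float(np.sum((np.abs(A @ b) - m_v) ** 2)))
        if best is None or history[-1] < best[1][-1]:
            best = (b, history)
    return DriveVector(best[0]), np.array(best[1])


def field_cv(field: NetField, mask: np.ndarray) -> float:
    """Coefficient of variation of |B1+| over the mask (population sd / mean)."""
    if not np.any(mask):
        raise ValueError("mask is empty")
    v = np.abs(field.map)[mask]
    mean = v.mean()
    if mean == 0:
        raise ValueError("undefined CV: field has zero mean over the mask")
    return float(v.std() / mean)


def synthetic_element_fields(
    M: int,
    K: int = 8,
    effective_wavelength: float | None = None,
    decay_scale: float | None = None,
    seed: int = 0,
    ring_radius: float | None = None,
    amplitude: float = 1.0,
) -> ElementFieldSet:
    """Analytic ring of K decaying-wave sources on an M x M grid.

    Element ``k`` sits at azimuth ``k * 2pi/K`` on a ring just outside the
    field of view; its field is ``A * exp(-r/decay) * exp(-2i pi r/lambda)``
    with ``r`` the distance from the element.  Short wavelengths produce the
    interference nulls characteristic of high-field transmit arrays.
    """
    if K < 2:
        raise ValueError(f"need at least 2 elements, got K={K}")
    wavelength = effective_wavelength if effective_wavelength else 0.9 * M
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    decay = decay_scale if decay_scale else 0.8 * M
    radius = ring_radius if ring_radius else 0.62 * M
    rng = np.random.default_rng(seed)
    amp_jitter = 1.0 + 0.02 * rng.standard_normal(K)

    yy, xx = np.mgrid[0:M, 0:M]
    cx = cy = (M - 1) / 2.0
    alpha = 2.0 * math.pi / K
    fields = np.empty((K, M, M), dtype=complex)
    positions = np.empty((K, 2))
    for k in range(K):
        ex = cx + radius * math.cos(k * alpha)
        ey = cy + radius * math.sin(k * alpha)
        positions[k] = (ex, ey)
        r = np.hypot(xx - ex, yy - ey)
        # exp(-i k alpha): the transmit polarization rotates with the element
        # azimuth, which is what makes mode 1 add coherently at the centre
        fields[k] = (amplitude * amp_jitter[k] * np.exp(-r / decay)
                     * np.exp(-2j * math.pi * r / wavelength)
                     * np.exp(-1j * k * alpha))
    return ElementFieldSet(fields, positions)


def default_illuminations(M: int, peak_b1: float = 6.0, K: int = 8,
                          seed: int = 0) -> tuple:
    """Two complementary net fields (CP and gradient mode) scaled to ``peak_b1``.

    The CP mode is centre-bright; the gradient mode has a central void.  Their
    nulls do not overlap, which is the property the interleaved sequence
    exploits.
    """
    S = synthetic_element_fields(M, K=K, seed=seed)
    cp = combine(S, mode_weights(K, 1)).map
    grad = combine(S, mode_weights(K, 2)).map
    return (NetField(cp * (peak_b1 / np.abs(cp).max()), provenance="cp_mode"),
            NetField(grad * (peak_b1 / np.abs(grad).max()),
                     provenance="gradient_mode"))
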