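"""Extended-phase-graph (EPG) simulation of voxel fingerprints.

Magnetization is decomposed into configuration states ``(F+_k, F-_k, Z_k)``
indexed by the gradient dephasing order ``k``.  ``F-_k`` stores the complex
conjugate of the transverse state at order ``-k`` so that an RF pulse acts as
the same 3x3 mixing matrix at every order.  Phase convention: a 90deg pulse
with phase 0 applied to equilibrium produces ``F+_0 = -1j * m0``.

The module provides the elementary operators (:func:`apply_rf`,
:func:`evolve`), a full-schedule fingerprint simulator
(:func:`simulate_fingerprint`), and slice-profile construction from the RF
waveform (:func:`slice_profile_from_pulse`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfigurationState",
    "TissueParams",
    "SliceProfile",
    "equilibrium_state",
    "apply_rf",
    "evolve",
    "rf_rotation_matrix",
    "simulate_fingerprint",
    "slice_profile_from_pulse",
]

#: Population fraction at the highest order above which truncation is flagged.
_TRUNCATION_TOL = 1e-12


@dataclass
class TissueParams:
    """Relaxation times (ms) and relative proton density of one tissue."""

    t1: float
    t2: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValueError(f"t1 and t2 must be positive, got t1={self.t1}, t2={self.t2}")
        if self.m0 < 0:
            raise ValueError(f"m0 must be non-negative, got {self.m0}")


@dataclass
class SliceProfile:
    """Discretized through-slice excitation profile.

    ``relative_flip_scales[i]`` multiplies the nominal flip angle of every
    pulse for sub-slice isochromat ``i``; ``weights`` sum to one.
    """

    relative_flip_scales: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.relative_flip_scales = np.asarray(self.relative_flip_scales, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.relative_flip_scales.shape != self.weights.shape:
            raise ValueError("scales and weights must have the same length")
        if np.any(self.relative_flip_scales < 0) or np.any(self.weights < 0):
            raise ValueError("scales and weights must be non-negative")
        s = self.weights.sum()
        if not math.isclose(s, 1.0, rel_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {s}")

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class ConfigurationState:
    """EPG state vectors over dephasing orders ``0..K`` for one isochromat family."""

    f_plus: np.ndarray
    f_minus: np.ndarray
    z: np.ndarray
    m0: float = 1.0
    truncated: bool = False

    def __post_init__(self) -> None:
        self.f_plus = np.asarray(self.f_plus, dtype=complex)
        self.f_minus = np.asarray(self.f_minus, dtype=complex)
        self.z = np.asarray(self.z, dtype=complex)
        if not (self.f_plus.shape == self.f_minus.shape == self.z.shape):
            raise ValueError("f_plus, f_minus and z must share a shape")
        if self.m0 < 0:
            raise ValueError("m0 must be non-negative")

    @property
    def max_order(self) -> int:
        return len(self.f_plus) - 1

    def copy(self) -> "ConfigurationState":
        return ConfigurationState(
            self.f_plus.copy(), self.f_minus.copy(), self.z.copy(), self.m0, self.truncated
        )


def equilibrium_state(m0: float = 1.0, max_order: int = 32) -> ConfigurationState:
    """Thermal equilibrium: no transverse states, ``z[0] = m0``."""
    n = max_order + 1
    z = np.zeros(n, dtype=complex)
    z[0] = m0
    return ConfigurationState(np.zeros(n, complex), np.zeros(n, complex), z, m0)


def rf_rotation_matrix(flip: float, phase: float) -> np.ndarray:
    """3x3 mixing matrix acting on ``(F+_k, F-_k, Z_k)`` at every order."""
    a, p = float(flip), float(phase)
    ca2 = math.cos(a / 2.0) ** 2
    sa2 = math.sin(a / 2.0) ** 2
    sa = math.sin(a)
    ca = math.cos(a)
    eip = complex(math.cos(p), math.sin(p))
    return np.array(
        [
            [ca2, eip * eip * sa2, -1j * eip * sa],
            [np.conj(eip * eip) * sa2, ca2, 1j * np.conj(eip) * sa],
            [-0.5j * np.conj(eip) * sa, 0.5j * eip * sa, ca],
        ],
        dtype=complex,
    )


def apply_rf(state: ConfigurationState, flip: float, phase: float) -> ConfigurationState:
    """Rotate all configuration states by an instantaneous RF pulse."""
    if not (math.isfinite(flip) and math.isfinite(phase)):
        raise ValueError(f"flip and phase must be finite, got flip={flip}, phase={phase}")
    t = rf_rotation_matrix(flip, phase)
    stacked = np.vstack([state.f_plus, state.f_minus, state.z])
    out = t @ stacked
    return ConfigurationState(out[0], out[1], out[2], state.m0, state.truncated)


def evolve(
    state: ConfigurationState,
    tau: float,
    tissue: TissueParams,
    spoiler_shifts: int = 0,
) -> ConfigurationState:
    """Relax for ``tau`` ms, then apply ``spoiler_shifts`` unit gradient shifts.

    Transverse orders decay with T2, longitudinal orders with T1; ``z[0]``
    regrows toward ``tissue.m0``.  Each shift moves ``F+_k -> F+_{k+1}`` with
    the standard wrap of ``F-`` through order zero.  Population pushed past
    the highest stored order sets the ``truncated`` flag on the result.
    """
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau}")
    if spoiler_shifts < 0:
        raise ValueError(f"spoiler_shifts must be non-negative, got {spoiler_shifts}")
    e2 = math.exp(-tau / tissue.t2)
    e1 = math.exp(-tau / tissue.t1)
    fp = state.f_plus * e2
    fm = state.f_minus * e2
    z = state.z * e1
    z[0] += (1.0 - e1) * tissue.m0
    truncated = state.truncated
    for _ in range(spoiler_shifts):
        if abs(fp[-1]) > _TRUNCATION_TOL:
            truncated = True
        fp = np.roll(fp, 1)
        fp[0] = 0.0
        fm = np.roll(fm, -1)
        fm[-1] = 0.0
        fp[0] = np.conj(fm[0])
    return ConfigurationState(fp, fm, z, state.m0, truncated)


def simulate_fingerprint(
    schedule,
    tissue: TissueParams,
    b1_amplitudes,
    profile: SliceProfile | None = None,
) -> np.ndarray:
    """Simulate the demodulated echo signal of one voxel over a schedule.

    Parameters
    ----------
    schedule : SequenceSchedule
        Sequence description (see :mod:`pnpmrf.schedule`).
    tissue : TissueParams
        Relaxation times and proton density of the voxel.
    b1_amplitudes : sequence of complex
        Per-transmit-channel B1+ in microtesla per unit drive.  The achieved
        flip of excitation ``n`` is ``drive_n * |b1[coil_n]| / reference_b1 *
        reference_flip_at_unit_drive``; the transmit phase adds ``arg(b1)``.
    profile : SliceProfile, optional
        Through-slice discretization; the output is the weighted sum of the
        sub-slice signals.

    Returns
    -------
    numpy.ndarray
        Complex vector of length ``schedule.n_excitations``: ``F+_0``
        sampled after the TE evolution, demodulated by the schedule RF phase.
    """
    b1 = np.asarray(b1_amplitudes, dtype=complex)
    if b1.shape != (schedule.n_channels,):
        raise ValueError(
            f"b1 must have {schedule.n_channels} channels, got shape {b1.shape}"
        )
    if profile is None:
        scales = np.array([1.0])
        weights = np.array([1.0])
    else:
        scales = profile.relative_flip_scales
        weights = profile.weights

    n = schedule.n_excitations
    out = np.zeros(n, dtype=complex)
    for scale, weight in zip(scales, weights):
        if weight == 0.0:
            continue
        out += weight * _simulate_single(schedule, tissue, b1, scale)
    return out


def _simulate_single(schedule, tissue: TissueParams, b1: np.ndarray, flip_scale: float) -> np.ndarray:
    n = schedule.n_excitations
    # one shift per TR plus one per inter-segment delay
    max_order = n + len(schedule.inter_segment_delays) + 1
    state = equilibrium_state(tissue.m0, max_order)
    te = schedule.te
    signal = np.zeros(n, dtype=complex)
    b1_mag = np.abs(b1)
    b1_arg = np.angle(b1)
    seg_of = schedule.segment_ids
    delays = schedule.inter_segment_delays
    for i, exc in enumerate(schedule.excitations):
        flip = (
            exc.relative_drive
            * (b1_mag[exc.coil_id] / schedule.reference_b1)
            * schedule.reference_flip_at_unit_drive
            * flip_scale
        )
        phase = exc.rf_phase + b1_arg[exc.coil_id]
        state = apply_rf(state, flip, phase)
        state = evolve(state, te, tissue, spoiler_shifts=0)
        signal[i] = state.f_plus[0] * np.exp(-1j * exc.rf_phase)
        state = evolve(state, exc.tr_to_next - te, tissue, spoiler_shifts=1)
        if i + 1 < n and seg_of[i + 1] != seg_of[i]:
            state = evolve(state, delays[seg_of[i] - 1], tissue, spoiler_shifts=1)
    return signal


def slice_profile_from_pulse(
    duration: float,
    time_bandwidth: float,
    shape: str = "sinc",
    n_subslices: int = 33,
) -> SliceProfile:
    """Build a slice profile from the Fourier transform of the RF waveform.

    The waveform is sampled over its duration, Fourier transformed, and the
    magnitude is sampled at ``n_subslices`` positions spanning +-1 slice
    thickness about the slice centre.  Scales are normalized so the centre of
    the slice has scale 1; weights are uniform.
    """
    if n_subslices < 1:
        raise ValueError(f"n_subslices must be >= 1, got {n_subslices}")
    if shape not in ("sinc", "rect"):
        raise ValueError(f"unsupported pulse shape {shape!r}")
    if n_subslices == 1:
        return SliceProfile(np.array([1.0]), np.array([1.0]))

    n_t = 1024
    t = (np.arange(n_t) / n_t - 0.5) * duration  # ms, centred
    if shape == "rect":
        waveform = np.ones(n_t)
    else:
        # Hann-apodized sinc (the standard slice-selective pulse); the
        # apodization suppresses the Gibbs ripple of a truncated sinc so the
        # profile is maximal at the slice centre
        bw = time_bandwidth / duration  # kHz
        waveform = np.sinc(bw * t) * (0.5 + 0.5 * np.cos(2 * np.pi * t / duration))

    # slice positions in units of slice thickness; bandwidth maps to 1 thickness
    positions = np.linspace(-1.0, 1.0, n_subslices)
    bw = time_bandwidth / duration
    freqs = positions * bw  # kHz offsets across +-1 thickness
    # small-tip approximation: flip profile ~ |FT of waveform| at each offset
    phase = np.exp(-2j * np.pi * np.outer(freqs, t))
    response = np.abs(phase @ waveform)
    centre = np.abs(np.sum(waveform))
    scales = response / centre
    weights = np.full(n_subslices, 1.0 / n_subslices)
    return SliceProfile(scales, weights)
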