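"""Brute-force isochromat Bloch simulation (validation oracle for the EPG).

An ensemble of spins on a deterministic uniform dephasing grid is rotated in
3-D by each pulse and precessed by each gradient spoiler event; the net
transverse magnetization equals the EPG's order-zero state as long as the
spin count exceeds twice the highest populated dephasing order.  Kept free
of any EPG machinery so the two implementations are independent.
"""

from __future__ import annotations

import numpy as np

from .epg import TissueParams

__all__ = ["rotate", "simulate_fingerprint_isochromat"]


def rotate(mxy: np.ndarray, mz: np.ndarray, flip: float, phase: float) -> tuple:
    """Rotate magnetization by ``flip`` about the transverse axis at ``phase``.

    Cartesian 3-D rotation Rz(phase) @ Rx(flip) @ Rz(-phase), with Rx mapping
    +z toward -y (so a 90deg, phase-0 pulse yields Mxy = -i).
    """
    c, s = np.cos(flip), np.sin(flip)
    cp, sp = np.cos(phase), np.sin(phase)
    rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    rx = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    r = rz @ rx @ rz.T
    m = np.stack([mxy.real, mxy.imag, np.asarray(mz, dtype=float)])
    out = r @ m
    return out[0] + 1j * out[1], out[2]


def simulate_fingerprint_isochromat(
    schedule,
    tissue: TissueParams,
    b1_amplitudes,
    n_spins: int = 2048,
) -> np.ndarray:
    """Full Bloch simulation of one voxel over a schedule.

    Spins are uniformly distributed over one spoiler dephasing period; each
    spoiler event advances spin ``i`` by ``2 pi i / n_spins``.
    """
    b1 = np.asarray(b1_amplitudes, dtype=complex)
    theta = 2.0 * np.pi * np.arange(n_spins) / n_spins
    dephase = np.exp(1j * theta)
    mxy = np.zeros(n_spins, dtype=complex)
    mz = np.full(n_spins, float(tissue.m0))
    seg = schedule.segment_ids
    delays = schedule.inter_segment_delays
    sig = np.zeros(schedule.n_excitations, dtype=complex)

    def relax(mxy, mz, tau):
        e2 = np.exp(-tau / tissue.t2)
        e1 = np.exp(-tau / tissue.t1)
        return mxy * e2, mz * e1 + (1.0 - e1) * tissue.m0

    for i, exc in enumerate(schedule.excitations):
        flip = (exc.relative_drive * (abs(b1[exc.coil_id]) / schedule.reference_b1)
                * schedule.reference_flip_at_unit_drive)
        phase = exc.rf_phase + np.angle(b1[exc.coil_id])
        mxy, mz = rotate(mxy, mz, flip, phase)
        mxy, mz = relax(mxy, mz, schedule.te)
        sig[i] = mxy.mean() * np.exp(-1j * exc.rf_phase)
        mxy, mz = relax(mxy, mz, exc.tr_to_next - schedule.te)
        mxy = mxy * dephase
        if i + 1 < schedule.n_excitations and seg[i + 1] != seg[i]:
            mxy, mz = relax(mxy, mz, delays[seg[i] - 1])
            mxy = mxy * dephase
    return sig
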