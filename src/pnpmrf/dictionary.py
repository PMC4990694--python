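"""4-D fingerprint dictionary: parameter grid, batch simulation, compression.

The dictionary spans T1, T2 and the B1+ amplitude of each of the two
transmit channels.  Raw 480-sample complex fingerprints are compressed by
view sharing: sets of 15 consecutive same-coil complex samples are summed
and the modulus taken, reducing each fingerprint to 32 real values (a 30x
storage reduction: 960 reals -> 32 reals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit, prange

from . import epg
from .schedule import SequenceSchedule, coil_sequence

__all__ = [
    "ParameterGrid",
    "CompressionPlan",
    "CompressedFingerprint",
    "Dictionary",
    "make_axes",
    "reduced_grid",
    "compression_plan",
    "compress",
    "build_dictionary",
    "simulate_fingerprints_batch",
    "save_dictionary",
    "load_dictionary",
]

BIN_SIZE = 15
N_BINS = 32

#: refuse to build dictionaries whose atom matrix would exceed this many bytes
ATOM_BUDGET_BYTES = 2 * 1024**3


class ResourceBudgetError(RuntimeError):
    """Raised when a requested dictionary would not fit the storage budget."""


@dataclass
class ParameterGrid:
    """Axes of the 4-D dictionary (T1 ms, T2 ms, B1 uT per channel)."""

    t1_values: np.ndarray
    t2_values: np.ndarray
    b1_values_per_channel: list  # one uT vector per channel

    def __post_init__(self) -> None:
        self.t1_values = np.asarray(self.t1_values, dtype=float)
        self.t2_values = np.asarray(self.t2_values, dtype=float)
        self.b1_values_per_channel = [
            np.asarray(v, dtype=float) for v in self.b1_values_per_channel
        ]
        for name, ax in self._axes():
            if len(ax) > 1 and np.any(np.diff(ax) <= 0):
                raise ValueError(f"{name} axis must be strictly increasing")

    def _axes(self):
        yield "t1", self.t1_values
        yield "t2", self.t2_values
        for c, v in enumerate(self.b1_values_per_channel):
            yield f"b1_ch{c}", v

    @property
    def n_channels(self) -> int:
        return len(self.b1_values_per_channel)

    @property
    def shape(self) -> tuple:
        return (len(self.t1_values), len(self.t2_values),
                *(len(v) for v in self.b1_values_per_channel))

    @property
    def n_entries(self) -> int:
        return int(np.prod(self.shape))

    def entry_tuples(self) -> np.ndarray:
        """All (t1, t2, b1_0, b1_1) tuples, row-major over the axes."""
        mesh = np.meshgrid(self.t1_values, self.t2_values,
                           *self.b1_values_per_channel, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def snap(self, t1, t2, b1):
        """Snap values to the nearest grid point on each axis."""
        def nearest(ax, v):
            return ax[np.argmin(np.abs(ax[:, None] - np.atleast_1d(v)[None, :]), axis=0)]
        return (nearest(self.t1_values, t1), nearest(self.t2_values, t2),
                [nearest(self.b1_values_per_channel[c], b1[c])
                 for c in range(self.n_channels)])


def make_axes(
    t1_min: float = 150.0,
    t1_max: float = 4564.0,
    t2_min: float = 15.0,
    t2_max: float = 456.0,
    relaxation_ratio: float = 1.05,
    b1_min: float = 0.0,
    b1_max: float = 15.0,
    b1_step: float = 0.2,
    n_channels: int = 2,
) -> ParameterGrid:
    """Default dictionary axes: 5% geometric T1/T2 steps, 0.2 uT B1 steps."""
    for lo, hi, what in ((t1_min, t1_max, "t1"), (t2_min, t2_max, "t2"),
                         (b1_min, b1_max, "b1")):
        if not lo < hi:
            raise ValueError(f"inverted {what} range: [{lo}, {hi}]")
    if relaxation_ratio <= 1.0 or b1_step <= 0:
        raise ValueError("relaxation_ratio must exceed 1 and b1_step be positive")

    def geometric(lo, hi):
        # the printed endpoint is the grid value nearest the stated maximum
        # (4564 rounds 150*1.05^70 up, 456 rounds 15*1.05^70 down)
        n = int(round(math.log(hi / lo) / math.log(relaxation_ratio)))
        return lo * relaxation_ratio ** np.arange(n + 1)

    n_b1 = int(round((b1_max - b1_min) / b1_step))
    b1 = np.linspace(b1_min, b1_max, n_b1 + 1)
    return ParameterGrid(geometric(t1_min, t1_max), geometric(t2_min, t2_max),
                         [b1.copy() for _ in range(n_channels)])


def reduced_grid(
    n_t1: int = 8, n_t2: int = 8, b1_indices=(10, 20, 30, 40),
    full: ParameterGrid | None = None,
) -> ParameterGrid:
    """True sub-grid of the full axes (shared tuples keep identical atoms)."""
    g = full or make_axes()
    t1_idx = np.unique(np.linspace(0, len(g.t1_values) - 1, n_t1).round().astype(int))
    t2_idx = np.unique(np.linspace(0, len(g.t2_values) - 1, n_t2).round().astype(int))
    b1_idx = np.asarray(b1_indices, dtype=int)
    return ParameterGrid(
        g.t1_values[t1_idx], g.t2_values[t2_idx],
        [v[b1_idx] for v in g.b1_values_per_channel],
    )


@dataclass
class CompressionPlan:
    """Partition of the excitation indices into same-coil bins of 15."""

    bin_coil_ids: np.ndarray  # (n_bins,)
    bin_indices: np.ndarray  # (n_bins, BIN_SIZE) excitation indices
    n_input: int

    @property
    def n_bins(self) -> int:
        return len(self.bin_coil_ids)

    def matrix(self) -> np.ndarray:
        """0/1 aggregation matrix of shape (n_input, n_bins)."""
        p = np.zeros((self.n_input, self.n_bins))
        for b in range(self.n_bins):
            p[self.bin_indices[b], b] = 1.0
        return p


@dataclass
class CompressedFingerprint:
    values: np.ndarray  # (n_bins,) real, non-negative
    plan: CompressionPlan


def compression_plan(coil_seq) -> CompressionPlan:
    """Group consecutive occurrences of each coil into bins of 15.

    Within the alternating segments "consecutive" means consecutive
    occurrences of the same coil (every other echo); bins are ordered by the
    index of their first contributing excitation.
    """
    coil_seq = np.asarray(coil_seq, dtype=int)
    bins = []
    for coil in np.unique(coil_seq):
        occ = np.flatnonzero(coil_seq == coil)
        if len(occ) % BIN_SIZE != 0:
            orphan = occ[(len(occ) // BIN_SIZE) * BIN_SIZE]
            raise ValueError(
                f"coil {coil}: {len(occ)} occurrences not divisible into bins of "
                f"{BIN_SIZE}; first unpartitionable excitation index {orphan}"
            )
        for start in range(0, len(occ), BIN_SIZE):
            chunk = occ[start:start + BIN_SIZE]
            bins.append((int(chunk[0]), int(coil), chunk))
    bins.sort(key=lambda b: b[0])
    return CompressionPlan(
        bin_coil_ids=np.array([b[1] for b in bins], dtype=int),
        bin_indices=np.stack([b[2] for b in bins]),
        n_input=len(coil_seq),
    )


def compress(fingerprint, plan: CompressionPlan) -> CompressedFingerprint:
    """Per bin: complex sum of its 15 samples, then modulus."""
    f = np.asarray(fingerprint)
    if f.shape[-1] != plan.n_input:
        raise ValueError(
            f"fingerprint length {f.shape[-1]} does not match plan input "
            f"length {plan.n_input}"
        )
    sums = f[..., plan.bin_indices].sum(axis=-1)
    return CompressedFingerprint(np.abs(sums), plan)


def compress_batch(fingerprints: np.ndarray, plan: CompressionPlan) -> np.ndarray:
    """Vectorized :func:`compress` for a (n, n_input) array -> (n, n_bins)."""
    if fingerprints.shape[1] != plan.n_input:
        raise ValueError("fingerprint length does not match plan")
    return np.abs(fingerprints[:, plan.bin_indices].sum(axis=2))


# ---------------------------------------------------------------------------
# batch EPG kernel


@njit(cache=True, parallel=True)
def _epg_batch_kernel(drives, coils, phases, trs, seg_ids, delays, te,
                      t1s, t2s, b1_pairs, ref_b1, ref_flip, flip_scale, out):
    n_exc = drives.shape[0]
    n_entries = t1s.shape[0]
    k_max = n_exc + delays.shape[0] + 2
    for e in prange(n_entries):
        t1 = t1s[e]
        t2 = t2s[e]
        fp = np.zeros(k_max + 1, dtype=np.complex128)
        fm = np.zeros(k_max + 1, dtype=np.complex128)
        z = np.zeros(k_max + 1, dtype=np.complex128)
        z[0] = 1.0
        active = 1
        for i in range(n_exc):
            b1 = b1_pairs[e, coils[i]]
            flip = drives[i] * (b1 / ref_b1) * ref_flip * flip_scale
            ph = phases[i]
            ca2 = np.cos(flip / 2.0) ** 2
            sa2 = np.sin(flip / 2.0) ** 2
            sa = np.sin(flip)
            ca = np.cos(flip)
            eip = np.cos(ph) + 1j * np.sin(ph)
            e2ip = eip * eip
            t00 = ca2
            t01 = e2ip * sa2
            t02 = -1j * eip * sa
            t10 = np.conj(e2ip) * sa2
            t11 = ca2
            t12 = 1j * np.conj(eip) * sa
            t20 = -0.5j * np.conj(eip) * sa
            t21 = 0.5j * eip * sa
            t22 = ca
            for k in range(active):
                a = fp[k]
                b = fm[k]
                c = z[k]
                fp[k] = t00 * a + t01 * b + t02 * c
                fm[k] = t10 * a + t11 * b + t12 * c
                z[k] = t20 * a + t21 * b + t22 * c
            # relax TE (no shift), sample echo
            e2 = np.exp(-te / t2)
            e1 = np.exp(-te / t1)
            for k in range(active):
                fp[k] *= e2
                fm[k] *= e2
                z[k] *= e1
            z[0] += 1.0 - e1
            out[e, i] = fp[0] * (np.cos(phases[i]) - 1j * np.sin(phases[i]))
            # relax TR-TE, then one spoiler shift
            tau = trs[i] - te
            e2 = np.exp(-tau / t2)
            e1 = np.exp(-tau / t1)
            for k in range(active):
                fp[k] *= e2
                fm[k] *= e2
                z[k] *= e1
            z[0] += 1.0 - e1
            if active < k_max:
                active += 1
            for k in range(active - 1, 0, -1):
                fp[k] = fp[k - 1]
            for k in range(active - 1):
                fm[k] = fm[k + 1]
            fm[active - 1] = 0.0
            fp[0] = np.conj(fm[0])
            # inter-segment recovery delay with one spoiler shift
            if i + 1 < n_exc and seg_ids[i + 1] != seg_ids[i]:
                tau = delays[seg_ids[i] - 1]
                e2 = np.exp(-tau / t2)
                e1 = np.exp(-tau / t1)
                for k in range(active):
                    fp[k] *= e2
                    fm[k] *= e2
                    z[k] *= e1
                z[0] += 1.0 - e1
                if active < k_max:
                    active += 1
                for k in range(active - 1, 0, -1):
                    fp[k] = fp[k - 1]
                for k in range(active - 1):
                    fm[k] = fm[k + 1]
                fm[active - 1] = 0.0
                fp[0] = np.conj(fm[0])


def simulate_fingerprints_batch(
    schedule: SequenceSchedule,
    t1s,
    t2s,
    b1_pairs,
    profile: epg.SliceProfile | None = None,
) -> np.ndarray:
    """Simulate many unit-PD fingerprints at once (numba-parallel EPG).

    ``b1_pairs`` is an (n, n_channels) array of B1 amplitudes in uT.  Agrees
    with :func:`pnpmrf.epg.simulate_fingerprint` to machine precision.
    """
    t1s = np.ascontiguousarray(t1s, dtype=np.float64)
    t2s = np.ascontiguousarray(t2s, dtype=np.float64)
    b1_pairs = np.ascontiguousarray(b1_pairs, dtype=np.float64)
    if b1_pairs.shape != (len(t1s), schedule.n_channels):
        raise ValueError("b1_pairs must be (n_entries, n_channels)")
    drives = np.ascontiguousarray(schedule.drives)
    coils = np.ascontiguousarray(coil_sequence(schedule))
    phases = np.ascontiguousarray(schedule.rf_phases)
    trs = np.ascontiguousarray(schedule.trs)
    seg_ids = np.ascontiguousarray(schedule.segment_ids)
    delays = np.ascontiguousarray(schedule.inter_segment_delays, dtype=np.float64)

    if profile is None:
        scales = np.array([1.0])
        weights = np.array([1.0])
    else:
        scales = profile.relative_flip_scales
        weights = profile.weights
    out = np.zeros((len(t1s), schedule.n_excitations), dtype=np.complex128)
    buf = np.zeros_like(out)
    for scale, weight in zip(scales, weights):
        if weight == 0.0:
            continue
        buf[:] = 0.0
        _epg_batch_kernel(drives, coils, phases, trs, seg_ids, delays,
                          float(schedule.te), t1s, t2s, b1_pairs,
                          float(schedule.reference_b1),
                          float(schedule.reference_flip_at_unit_drive),
                          float(scale), buf)
        out += weight * buf
    return out


# ---------------------------------------------------------------------------
# dictionary build


@dataclass
class Dictionary:
    """Compressed, unit-normalized dictionary plus matching metadata."""

    grid: ParameterGrid
    atoms: np.ndarray  # (n_entries, n_bins) unit l2 rows (valid entries)
    atom_norms: np.ndarray  # pre-normalization compressed norms
    valid: np.ndarray  # bool; False for degenerate (zero-signal) entries
    plan: CompressionPlan
    schedule_hash: str

    @property
    def n_entries(self) -> int:
        return self.atoms.shape[0]

    def entry_parameters(self) -> np.ndarray:
        return self.grid.entry_tuples()


def build_dictionary(
    grid: ParameterGrid,
    schedule: SequenceSchedule,
    profile: epg.SliceProfile | None = None,
    chunk_size: int = 8192,
    progress: bool = False,
) -> Dictionary:
    """Simulate, compress and normalize every grid entry.

    Output is deterministic and independent of ``chunk_size``.  Entries whose
    compressed fingerprint is identically zero (for example both B1 values
    zero) are kept but flagged invalid so matching skips them.
    """
    plan = compression_plan(coil_sequence(schedule))
    n = grid.n_entries
    need = n * plan.n_bins * 8
    if need > ATOM_BUDGET_BYTES:
        raise ResourceBudgetError(
            f"dictionary atoms would need {need / 1e9:.1f} GB "
            f"(> {ATOM_BUDGET_BYTES / 1e9:.1f} GB budget); reduce the grid"
        )
    params = grid.entry_tuples()
    atoms = np.empty((n, plan.n_bins))
    for start in range(0, n, chunk_size):
        stop = min(start + chunk_size, n)
        chunk = params[start:stop]
        raw = simulate_fingerprints_batch(
            schedule, chunk[:, 0], chunk[:, 1], chunk[:, 2:], profile
        )
        atoms[start:stop] = compress_batch(raw, plan)
        if progress:
            print(f"dictionary: {stop}/{n} entries", flush=True)
    norms = np.linalg.norm(atoms, axis=1)
    valid = norms > 1e-12
    atoms[valid] /= norms[valid, None]
    atoms[~valid] = 0.0
    return Dictionary(grid, atoms, norms, valid, plan, schedule.content_hash())


def save_dictionary(path, d: Dictionary) -> None:
    """Write the dictionary container (HDF5)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = 1
        f.attrs["schedule_hash"] = d.schedule_hash
        f.create_dataset("atoms", data=d.atoms, chunks=True)
        f.create_dataset("atom_norms", data=d.atom_norms)
        f.create_dataset("valid", data=d.valid)
        f.create_dataset("axes/t1", data=d.grid.t1_values)
        f.create_dataset("axes/t2", data=d.grid.t2_values)
        for c, v in enumerate(d.grid.b1_values_per_channel):
            f.create_dataset(f"axes/b1_ch{c}", data=v)
        f.create_dataset("plan/bin_coil_ids", data=d.plan.bin_coil_ids)
        f.create_dataset("plan/bin_indices", data=d.plan.bin_indices)
        f.attrs["plan_n_input"] = d.plan.n_input


def load_dictionary(path) -> Dictionary:
    import h5py

    with h5py.File(path, "r") as f:
        channels = sorted(k for k in f["axes"] if k.startswith("b1_ch"))
        grid = ParameterGrid(
            f["axes/t1"][:], f["axes/t2"][:],
            [f[f"axes/{c}"][:] for c in channels],
        )
        plan = CompressionPlan(
            f["plan/bin_coil_ids"][:], f["plan/bin_indices"][:],
            int(f.attrs["plan_n_input"]),
        )
        return Dictionary(
            grid, f["atoms"][:], f["atom_norms"][:], f["valid"][:].astype(bool),
            plan, str(f.attrs["schedule_hash"]),
        )
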