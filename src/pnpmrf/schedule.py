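"""Construction and validation of the four-segment interleaved sequence schedule.

The default schedule has 480 excitations in 4 segments of 120.  Segments 1
and 3 are RF-spoiled gradient echoes alternating between the two transmit
coil configurations echo-to-echo; segments 2 and 4 each dedicate a single
coil, use 0/180deg phase cycling and larger drives so stimulated echoes
contribute.  Long recovery delays separate the segments.
"""

from __future__ import annotations

import csv
import hashlib
import io
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ExcitationSpec",
    "SequenceSchedule",
    "ScheduleConfig",
    "build_default_schedule",
    "validate_schedule",
    "coil_sequence",
]

TR_MIN_MS = 4.8
TR_MAX_MS = 8.0
N_SEGMENTS = 4
EXCITATIONS_PER_SEGMENT = 120


@dataclass
class ExcitationSpec:
    """One excitation: which coil fires, how hard, with what phase and timing."""

    segment_id: int  # 1..4
    index_in_segment: int  # 0..119
    coil_id: int  # 0 or 1
    relative_drive: float  # nominal flip (rad) at the reference B1
    rf_phase: float  # rad
    tr_to_next: float  # ms
    spoiled: bool  # quadratic RF spoiling active


@dataclass
class ScheduleConfig:
    """Flat configuration for :func:`build_default_schedule`."""

    tr: float = 4.8  # ms
    te: float = 2.3  # ms
    inter_segment_delay: float = 3000.0  # ms
    peak_flip_alternating_deg: float = 25.0  # segments 1 and 3
    peak_flip_dedicated_deg: float = 60.0  # segments 2 and 4
    rf_spoil_increment_deg: float = 117.0
    reference_b1: float = 6.0  # uT at which relative_drive equals achieved flip
    rf_duration: float = 2.0  # ms
    rf_time_bandwidth: float = 3.0
    rf_shape: str = "sinc"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ScheduleConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(mapping) - known
        if bad:
            raise ValueError(f"unknown schedule config keys: {sorted(bad)}")
        kwargs = {}
        for k, v in mapping.items():
            if k == "rf_shape":
                kwargs[k] = str(v)
            else:
                kwargs[k] = float(v)
        return cls(**kwargs)


@dataclass
class SequenceSchedule:
    """Ordered description of all excitations plus global sequence constants."""

    excitations: list
    inter_segment_delays: list  # ms, one per segment boundary (3 entries)
    te: float  # ms
    rf_pulse: tuple  # (duration ms, time-bandwidth, shape)
    n_channels: int = 2
    reference_flip_at_unit_drive: float = 1.0  # rad at unit drive and reference B1
    reference_b1: float = 6.0  # uT

    @property
    def n_excitations(self) -> int:
        return len(self.excitations)

    @property
    def segment_ids(self) -> np.ndarray:
        return np.array([e.segment_id for e in self.excitations], dtype=int)

    @property
    def drives(self) -> np.ndarray:
        return np.array([e.relative_drive for e in self.excitations])

    @property
    def rf_phases(self) -> np.ndarray:
        return np.array([e.rf_phase for e in self.excitations])

    @property
    def trs(self) -> np.ndarray:
        return np.array([e.tr_to_next for e in self.excitations])

    def to_csv(self) -> str:
        """Canonical per-excitation table; floats use repr so round trips are exact."""
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(
            ["segment_id", "index_in_segment", "coil_id", "relative_drive",
             "rf_phase", "tr_to_next", "spoiled"]
        )
        for e in self.excitations:
            w.writerow(
                [e.segment_id, e.index_in_segment, e.coil_id, repr(e.relative_drive),
                 repr(e.rf_phase), repr(e.tr_to_next), int(e.spoiled)]
            )
        return buf.getvalue()

    @classmethod
    def from_csv(
        cls,
        text: str,
        inter_segment_delays,
        te: float,
        rf_pulse: tuple,
        n_channels: int = 2,
        reference_flip_at_unit_drive: float = 1.0,
        reference_b1: float = 6.0,
    ) -> "SequenceSchedule":
        rows = list(csv.reader(io.StringIO(text)))
        excitations = [
            ExcitationSpec(int(r[0]), int(r[1]), int(r[2]), float(r[3]),
                           float(r[4]), float(r[5]), bool(int(r[6])))
            for r in rows[1:]
        ]
        return cls(excitations, list(inter_segment_delays), te, rf_pulse,
                   n_channels, reference_flip_at_unit_drive, reference_b1)

    def content_hash(self) -> str:
        """Hash binding dictionaries to the exact schedule they were built for."""
        h = hashlib.sha256()
        h.update(self.to_csv().encode())
        h.update(repr((tuple(self.inter_segment_delays), self.te, self.rf_pulse,
                       self.n_channels, self.reference_flip_at_unit_drive,
                       self.reference_b1)).encode())
        return h.hexdigest()


def build_default_schedule(config: ScheduleConfig | None = None) -> SequenceSchedule:
    """Build the default 480-excitation schedule from a flat config.

    Flip trains are half-sine ramps per segment peaking at the configured
    nominal flips (stand-ins for the device-specific drive tables).
    """
    cfg = config or ScheduleConfig()
    violations = []
    if not (TR_MIN_MS <= cfg.tr <= TR_MAX_MS):
        violations.append(f"tr={cfg.tr} ms outside [{TR_MIN_MS}, {TR_MAX_MS}]")
    if not (0 < cfg.te < cfg.tr):
        violations.append(f"te={cfg.te} ms must lie in (0, tr)")
    if cfg.inter_segment_delay <= 0:
        violations.append("inter_segment_delay must be positive")
    if violations:
        raise ValueError("invalid schedule config: " + "; ".join(violations))

    n = EXCITATIONS_PER_SEGMENT
    inc = math.radians(cfg.rf_spoil_increment_deg)
    excitations = []
    for seg in range(1, N_SEGMENTS + 1):
        alternating = seg in (1, 3)
        peak = math.radians(
            cfg.peak_flip_alternating_deg if alternating else cfg.peak_flip_dedicated_deg
        )
        dedicated_coil = 0 if seg == 2 else 1
        for j in range(n):
            drive = peak * math.sin(math.pi * (j + 0.5) / n)
            if alternating:
                coil = j % 2
                phase = (inc * j * (j + 1) / 2.0) % (2.0 * math.pi)
                spoiled = True
            else:
                coil = dedicated_coil
                phase = 0.0 if j % 2 == 0 else math.pi
                spoiled = False
            excitations.append(
                ExcitationSpec(seg, j, coil, drive, phase, cfg.tr, spoiled)
            )
    return SequenceSchedule(
        excitations=excitations,
        inter_segment_delays=[cfg.inter_segment_delay] * (N_SEGMENTS - 1),
        te=cfg.te,
        rf_pulse=(cfg.rf_duration, cfg.rf_time_bandwidth, cfg.rf_shape),
        n_channels=2,
        reference_flip_at_unit_drive=1.0,
        reference_b1=cfg.reference_b1,
    )


def validate_schedule(s: SequenceSchedule) -> list:
    """Check every structural invariant; returns a list of violation strings."""
    v = []
    total = N_SEGMENTS * EXCITATIONS_PER_SEGMENT
    if s.n_excitations != total:
        v.append(f"count: expected {total} excitations, got {s.n_excitations}")
    seg_counts = {}
    for i, e in enumerate(s.excitations):
        seg_counts[e.segment_id] = seg_counts.get(e.segment_id, 0) + 1
        if e.coil_id not in (0, 1):
            v.append(f"excitation {i}: coil_id {e.coil_id} not in {{0,1}}")
        if not (TR_MIN_MS <= e.tr_to_next <= TR_MAX_MS):
            v.append(
                f"excitation {i}: tr_to_next {e.tr_to_next} ms outside "
                f"[{TR_MIN_MS}, {TR_MAX_MS}]"
            )
    for seg in range(1, N_SEGMENTS + 1):
        if seg_counts.get(seg, 0) != EXCITATIONS_PER_SEGMENT:
            v.append(
                f"segment {seg}: expected {EXCITATIONS_PER_SEGMENT} excitations, "
                f"got {seg_counts.get(seg, 0)}"
            )
    by_seg = {seg: [e for e in s.excitations if e.segment_id == seg]
              for seg in range(1, N_SEGMENTS + 1)}
    for seg in (1, 3):
        for i, e in enumerate(by_seg[seg]):
            if e.coil_id != i % 2:
                v.append(f"segment {seg} excitation {i}: alternation broken "
                         f"(coil {e.coil_id}, expected {i % 2})")
                break
        if any(not e.spoiled for e in by_seg[seg]):
            v.append(f"segment {seg}: all excitations must be RF-spoiled")
    for seg in (2, 4):
        coils = {e.coil_id for e in by_seg[seg]}
        if len(coils) > 1:
            v.append(f"segment {seg}: dedicated-coil rule broken, coils {sorted(coils)}")
        if any(e.spoiled for e in by_seg[seg]):
            v.append(f"segment {seg}: RF spoiling must be off (0/180 cycling)")
        for i, e in enumerate(by_seg[seg]):
            expect = 0.0 if i % 2 == 0 else math.pi
            if not math.isclose(e.rf_phase % (2 * math.pi), expect, abs_tol=1e-9):
                v.append(f"segment {seg} excitation {i}: phase must cycle 0/pi")
                break
    if by_seg[2] and by_seg[4] and by_seg[2][0].coil_id == by_seg[4][0].coil_id:
        v.append("segments 2 and 4 must use different dedicated coils")
    peak_alt = max((e.relative_drive for e in by_seg[1] + by_seg[3]), default=0.0)
    peak_ded = max((e.relative_drive for e in by_seg[2] + by_seg[4]), default=0.0)
    if by_seg[1] and by_seg[2] and peak_ded <= peak_alt:
        v.append("segments 2/4 must have larger peak relative_drive than 1/3")
    if len(s.inter_segment_delays) != N_SEGMENTS - 1:
        v.append(f"expected {N_SEGMENTS - 1} inter-segment delays, "
                 f"got {len(s.inter_segment_delays)}")
    return v


def coil_sequence(s: SequenceSchedule) -> np.ndarray:
    """Per-excitation coil id in acquisition order."""
    return np.array([e.coil_id for e in s.excitations], dtype=int)
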