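"""Voxel-wise exhaustive dictionary matching.

Correlation is the cosine similarity between the measured compressed
fingerprint (real, non-negative after the modulus projection) and the
unit-normalized dictionary atoms.  PD is the least-squares scale between the
un-normalized measured and simulated fingerprints, optionally corrected for
the receive magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dictionary import CompressedFingerprint, Dictionary, compress_batch

__all__ = ["ParameterMaps", "match_voxel", "match_fingerprints", "match_image"]

DEFAULT_MASK_FRACTION = 0.05  # of the 95th-percentile first-bin magnitude


@dataclass
class ParameterMaps:
    """Co-registered recovered maps."""

    pd: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    b1: np.ndarray  # (n_channels, M, M) uT
    correlation: np.ndarray
    mask: np.ndarray


def match_fingerprints(measured: np.ndarray, dictionary: Dictionary,
                       atom_block: int = 100_000) -> tuple:
    """Exhaustive search over atoms for a (V, n_bins) batch of fingerprints.

    Returns ``(best_index, correlation, pd)``.  All-zero fingerprints get
    index -1, correlation 0 and pd 0.  Ties break to the lowest atom index.
    """
    measured = np.asarray(measured, dtype=float)
    if measured.ndim != 2 or measured.shape[1] != dictionary.atoms.shape[1]:
        raise ValueError(
            f"measured must be (V, {dictionary.atoms.shape[1]}), got {measured.shape}"
        )
    if not np.any(dictionary.valid):
        raise ValueError("dictionary has no valid (non-degenerate) entries")
    norms = np.linalg.norm(measured, axis=1)
    nonzero = norms > 0
    unit = np.zeros_like(measured)
    unit[nonzero] = measured[nonzero] / norms[nonzero, None]

    n_atoms = dictionary.n_entries
    best_idx = np.full(len(measured), -1, dtype=np.int64)
    best_corr = np.zeros(len(measured))
    invalid = ~dictionary.valid
    for start in range(0, n_atoms, atom_block):
        stop = min(start + atom_block, n_atoms)
        corr = unit @ dictionary.atoms[start:stop].T
        corr[:, invalid[start:stop]] = -np.inf
        idx = np.argmax(corr, axis=1)
        val = corr[np.arange(len(measured)), idx]
        better = val > best_corr  # strict: ties keep the earlier block/index
        np.copyto(best_idx, idx + start, where=better)
        np.copyto(best_corr, val, where=better)
    best_corr = np.clip(best_corr, 0.0, 1.0)
    pd = np.zeros(len(measured))
    ok = nonzero & (best_idx >= 0)
    pd[ok] = (np.einsum("ij,ij->i", measured[ok], dictionary.atoms[best_idx[ok]])
              / dictionary.atom_norms[best_idx[ok]])
    best_idx[~nonzero] = -1
    best_corr[~nonzero] = 0.0
    return best_idx, best_corr, pd


def match_voxel(measured: CompressedFingerprint, dictionary: Dictionary) -> dict:
    """Match a single compressed fingerprint; see :func:`match_fingerprints`."""
    idx, corr, pd = match_fingerprints(measured.values[None, :], dictionary)
    if idx[0] < 0:
        return {"t1": 0.0, "t2": 0.0, "b1": [0.0] * dictionary.grid.n_channels,
                "pd": 0.0, "correlation": 0.0, "index": -1}
    params = np.unravel_index(idx[0], dictionary.grid.shape)
    g = dictionary.grid
    return {
        "t1": g.t1_values[params[0]],
        "t2": g.t2_values[params[1]],
        "b1": [g.b1_values_per_channel[c][params[2 + c]]
               for c in range(g.n_channels)],
        "pd": float(pd[0]),
        "correlation": float(corr[0]),
        "index": int(idx[0]),
    }


def match_image(
    series: np.ndarray,
    plan,
    dictionary: Dictionary,
    rx=None,
    schedule_hash: str | None = None,
    mask_fraction: float = DEFAULT_MASK_FRACTION,
) -> ParameterMaps:
    """Match every voxel of a combined image series.

    ``series`` is (T, M, M) complex with T either the raw excitation count
    (compressed here) or the number of compressed bins.  The PD map is
    divided by the root-sum-of-squares receive magnitude of ``rx`` when
    given.  A ``schedule_hash`` differing from the dictionary's is a hard
    error (wrong-dictionary guard).
    """
    if schedule_hash is not None and schedule_hash != dictionary.schedule_hash:
        raise ValueError("schedule hash does not match the dictionary; "
                         "refusing to match against the wrong dictionary")
    series = np.asarray(series)
    n_bins = dictionary.atoms.shape[1]
    if series.shape[0] == dictionary.plan.n_input:
        flat = series.reshape(series.shape[0], -1).T  # (V, T) complex
        compressed = compress_batch(flat, dictionary.plan)
    elif series.shape[0] == n_bins:
        compressed = np.abs(series.reshape(n_bins, -1)).T
    else:
        raise ValueError(
            f"series has {series.shape[0]} timepoints; expected "
            f"{dictionary.plan.n_input} (raw) or {n_bins} (compressed)"
        )
    shape = series.shape[1:]
    first_bin = compressed[:, 0]
    ref = np.percentile(first_bin, 95)
    mask_flat = first_bin > mask_fraction * ref
    if plan is not None and plan.n_bins != n_bins:
        raise ValueError("compression plan does not match dictionary bins")

    idx = np.full(compressed.shape[0], -1, dtype=np.int64)
    corr = np.zeros(compressed.shape[0])
    pd = np.zeros(compressed.shape[0])
    if np.any(mask_flat):
        i, c, p = match_fingerprints(compressed[mask_flat], dictionary)
        idx[mask_flat] = i
        corr[mask_flat] = c
        pd[mask_flat] = p
    matched = idx >= 0
    g = dictionary.grid
    sub = np.unravel_index(np.where(matched, idx, 0), g.shape)
    t1 = np.where(matched, g.t1_values[sub[0]], 0.0)
    t2 = np.where(matched, g.t2_values[sub[1]], 0.0)
    b1 = np.stack([np.where(matched, g.b1_values_per_channel[c][sub[2 + c]], 0.0)
                   for c in range(g.n_channels)])
    if rx is not None:
        rss = np.sqrt((np.abs(rx.maps) ** 2).sum(axis=0)).ravel()
        ok = rss > 0
        pd = np.where(ok, pd / np.where(ok, rss, 1.0), 0.0)
    mask = mask_flat.reshape(shape)
    zero = ~mask_flat
    for arr in (t1, t2, pd, corr):
        arr[zero] = 0.0
    b1[:, zero] = 0.0
    return ParameterMaps(
        pd=pd.reshape(shape), t1=t1.reshape(shape), t2=t2.reshape(shape),
        b1=b1.reshape(g.n_channels, *shape),
        correlation=corr.reshape(shape), mask=mask,
    )
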