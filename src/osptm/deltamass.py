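"""Delta-mass peak modelling and three-level target-decoy FDR.

An open search leaves each PSM with a precursor mass shift (delta mass).
Across a whole experiment these shifts pile up into narrow peaks, one
per modification (plus isotope satellites).  This module recalibrates
the shifts per sample, models the peaks from a kernel-smoothed density,
assigns PSMs to peaks, and filters identifications by target-decoy FDR
computed simultaneously at the global, local (1-Da bin) and peak level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .io import PSMRecord

logger = logging.getLogger(__name__)

#: half-width of the unmodified population used as recalibration anchor
ANCHOR_WINDOW_DA = 0.05
MIN_ANCHOR_PSMS = 50


@dataclass
class DeltaMassPeak:
    """One modelled peak in the delta-mass distribution."""

    peak_id: int
    apex: float
    left: float
    right: float
    psm_count: int
    psm_indices: np.ndarray  # indices into the PSM list used for detection

    def __post_init__(self) -> None:
        if not self.left < self.apex < self.right:
            raise ValueError(
                f"peak {self.peak_id}: bounds must satisfy left < apex < right"
            )


@dataclass
class FDRResult:
    """Per-PSM q-values at the global, local and peak strata."""

    q_global: np.ndarray
    q_local: np.ndarray
    q_peak: np.ndarray
    passed: np.ndarray  # bool; True iff all three q-values <= threshold
    threshold: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "q_global": self.q_global,
                "q_local": self.q_local,
                "q_peak": self.q_peak,
                "passed": self.passed,
            }
        )


def recalibrate(psms: list[PSMRecord]) -> tuple[list[PSMRecord], dict[str, float]]:
    """Remove per-sample systematic delta-mass offsets.

    The unmodified population (|dM| < 0.05 Da) of each sample serves as
    the anchor: its median delta mass is the sample's offset and is
    subtracted from every delta mass of that sample.  Samples with fewer
    than 50 anchor PSMs are left uncorrected with a warning.  Returns
    the corrected PSMs and the applied per-sample corrections.
    """
    by_sample: dict[str, list[float]] = {}
    for p in psms:
        if abs(p.delta_mass) < ANCHOR_WINDOW_DA:
            by_sample.setdefault(p.sample_id, []).append(p.delta_mass)
    corrections: dict[str, float] = {}
    for sample in sorted({p.sample_id for p in psms}):
        anchors = by_sample.get(sample, [])
        if len(anchors) < MIN_ANCHOR_PSMS:
            logger.warning(
                "sample %s: only %d anchor PSMs (<%d); no recalibration",
                sample, len(anchors), MIN_ANCHOR_PSMS,
            )
            corrections[sample] = 0.0
        else:
            corrections[sample] = float(np.median(anchors))
            logger.info("sample %s: delta-mass correction %.5f Da", sample, corrections[sample])
    corrected = [
        replace(p, delta_mass=p.delta_mass - corrections[p.sample_id]) for p in psms
    ]
    return corrected, corrections


def detect_peaks(
    psms: list[PSMRecord],
    bandwidth: float = 0.005,
    min_psm: int = 5,
    grid_step: float = 0.0005,
) -> list[DeltaMassPeak]:
    """Model peaks in the delta-mass distribution.

    The delta masses are histogrammed on a fine grid and smoothed with a
    Gaussian kernel of SD ``bandwidth``.  Local maxima of the smoothed
    density supported by at least ``min_psm`` PSMs become peaks; peak
    boundaries sit at the flanking density minima, and the apex is the
    mean delta mass of the member PSMs.  Peaks never overlap: adjacent
    peaks split at the minimum between them.
    """
    if not psms:
        return []
    dm = np.array([p.delta_mass for p in psms])
    lo, hi = dm.min() - 5 * bandwidth, dm.max() + 5 * bandwidth
    edges = np.arange(lo, hi + grid_step, grid_step)
    hist, edges = np.histogram(dm, bins=edges)
    density = gaussian_filter1d(hist.astype(float), sigma=bandwidth / grid_step)
    centers = 0.5 * (edges[:-1] + edges[1:])

    interior = (density[1:-1] > 0) & (density[1:-1] >= density[:-2]) & (density[1:-1] > density[2:])
    maxima = np.flatnonzero(interior) + 1
    if maxima.size == 0:
        return []

    # split points: density minimum between consecutive maxima
    splits = np.empty(maxima.size + 1)
    splits[0] = centers[0] - grid_step
    splits[-1] = centers[-1] + grid_step
    for k in range(maxima.size - 1):
        seg = slice(maxima[k], maxima[k + 1] + 1)
        splits[k + 1] = centers[maxima[k] + int(np.argmin(density[seg]))]

    order = np.argsort(dm, kind="stable")
    sorted_dm = dm[order]
    peaks: list[DeltaMassPeak] = []
    peak_id = 0
    for k in range(maxima.size):
        left, right = splits[k], splits[k + 1]
        i0, i1 = np.searchsorted(sorted_dm, [left, right])
        members = order[i0:i1]
        if members.size < min_psm:
            continue
        apex = float(dm[members].mean())
        if not left < apex < right:  # numerically degenerate sliver
            continue
        peaks.append(
            DeltaMassPeak(peak_id, apex, float(left), float(right), int(members.size), members)
        )
        peak_id += 1
    return peaks


def assign_to_peaks(psms: list[PSMRecord], peaks: list[DeltaMassPeak]) -> np.ndarray:
    """Peak id per PSM, or -1 for PSMs outside every peak window.

    Peak windows must not overlap (guaranteed by ``detect_peaks``).
    """
    bounds = sorted(((p.left, p.right, p.peak_id) for p in peaks))
    for (l1, r1, i1), (l2, r2, i2) in zip(bounds, bounds[1:]):
        if l2 < r1:
            raise ValueError(f"peaks {i1} and {i2} overlap")
    lefts = np.array([b[0] for b in bounds])
    rights = np.array([b[1] for b in bounds])
    ids = np.array([b[2] for b in bounds], dtype=int)
    dm = np.array([p.delta_mass for p in psms])
    out = np.full(len(psms), -1, dtype=int)
    if len(bounds) == 0:
        return out
    k = np.searchsorted(lefts, dm, side="right") - 1
    valid = (k >= 0) & (dm < rights[np.clip(k, 0, None)])
    out[valid] = ids[k[valid]]
    return out


def _stratum_qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Target-decoy q-values within one stratum.

    FDR(s) = #decoys(score >= s) / #targets(score >= s), monotonized to
    q-values by a cumulative minimum from the tail.  At tied scores
    decoys are ranked above targets (conservative).
    """
    n = scores.size
    if n == 0:
        return np.empty(0)
    if not is_decoy.any():
        return np.zeros(n)
    # sort descending by score; decoys first within ties
    order = np.lexsort((~is_decoy, -scores))
    dec_cum = np.cumsum(is_decoy[order])
    tgt_cum = np.cumsum(~is_decoy[order])
    # at tied scores every member of the tie group sees the full group
    sorted_scores = scores[order]
    _, inv, counts = np.unique(-sorted_scores, return_inverse=True, return_counts=True)
    group_end = np.cumsum(counts) - 1  # last index of each tie group
    dec_at = dec_cum[group_end][inv]
    tgt_at = tgt_cum[group_end][inv]
    fdr = dec_at / np.maximum(tgt_at, 1)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def fdr_filter(
    psms: list[PSMRecord],
    peaks: list[DeltaMassPeak],
    threshold: float = 0.01,
    peak_assignment: np.ndarray | None = None,
) -> FDRResult:
    """Three-level target-decoy FDR filter.

    Each PSM receives a q-value in three strata: globally, within its
    1-Da delta-mass bin, and within its assigned delta-mass peak.  A PSM
    passes only if all three q-values are at or below ``threshold``.
    PSMs not assigned to any peak cannot pass (their peak-level q-value
    is 1): only peak-supported identifications are validated.
    """
    scores = np.array([p.score for p in psms])
    is_decoy = np.array([p.is_decoy for p in psms])
    dm = np.array([p.delta_mass for p in psms])
    n = len(psms)
    if n and not is_decoy.any():
        logger.warning("no decoy PSMs: all q-values are 0")

    q_global = _stratum_qvalues(scores, is_decoy)

    q_local = np.empty(n)
    bins = np.round(dm).astype(int)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        q_local[idx] = _stratum_qvalues(scores[idx], is_decoy[idx])

    if peak_assignment is None:
        peak_assignment = assign_to_peaks(psms, peaks)
    q_peak = np.ones(n)
    for pid in np.unique(peak_assignment):
        if pid < 0:
            continue
        idx = np.flatnonzero(peak_assignment == pid)
        q_peak[idx] = _stratum_qvalues(scores[idx], is_decoy[idx])

    passed = (q_global <= threshold) & (q_local <= threshold) & (q_peak <= threshold)
    return FDRResult(q_global, q_local, q_peak, passed, threshold)


def peaks_frame(peaks: list[DeltaMassPeak]) -> pd.DataFrame:
    """Tab-delimited-ready peak table."""
    return pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in peaks],
            "apex": [p.apex for p in peaks],
            "left": [p.left for p in peaks],
            "right": [p.right for p in peaks],
            "psm_count": [p.psm_count for p in peaks],
        }
    )
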