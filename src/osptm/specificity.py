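"""Residue and sequence-quintile specificity of delta-mass peaks.

For each peak, the residue profile asks "which amino acid carries this
shift more often than its local sequence context would predict?": the
raw frequency of each modified residue type is corrected by the average
frequency of that residue at the three positions before and after the
modification site.  The quintile profile asks "where along the peptide
does the shift sit?": shifts concentrated in the first fifth of the
peptide sequence — on the newly generated peptide N-terminus, for
peptides that are not protein-N-terminal — betray artefacts introduced
during sample preparation or fragmentation rather than biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, PSMRecord

FLANK_OFFSETS = (-3, -2, -1, 1, 2, 3)

#: first-quintile share above which an internal-peptide shift is called
#: artefactual
ARTEFACT_Q1_THRESHOLD = 70.0
#: minimum PSMs for any origin call, and minimum internal-peptide PSMs
#: for an artefactual call
MIN_PSMS_FOR_CALL = 10
MIN_INTERNAL_PSMS = 5


@dataclass
class SpecificityProfile:
    """Residue and quintile specificity of one delta-mass peak."""

    peak_id: int
    n_psms: int
    raw: dict[str, float]  # % of peak PSMs per residue type (sums to 100)
    background: dict[str, float]  # flanking-context frequency, %
    corrected: dict[str, float]  # raw - background, percentage points
    quintiles: np.ndarray  # % per quintile 1..5 (sums to 100)
    origin: str = "unknown"  # {artefactual, biological, unknown}


def quintile_of(pos: int, length: int) -> int:
    """Sequence quintile (1..5) of a 1-based position in a peptide."""
    return min(5, (5 * (pos - 1)) // length + 1)


def residue_profile(peak_psms: list[PSMRecord]) -> tuple[dict[str, float], dict[str, float], dict[str, float], int]:
    """Raw, background and corrected residue frequencies of a peak.

    raw(a): % of modified PSMs carrying the shift on residue a.
    background(a): per PSM, the frequency of residue a among the up-to-
    six flanking positions (offsets within the peptide only), averaged
    over PSMs, as %.  corrected(a) = raw(a) - background(a).
    Unmodified PSMs are excluded; the count of excluded PSMs is not part
    of the profile.  Returns (raw, background, corrected, n_used).
    """
    raw_counts = {a: 0 for a in AMINO_ACIDS}
    bg_sum = {a: 0.0 for a in AMINO_ACIDS}
    n = 0
    for p in peak_psms:
        if p.mod_pos is None:
            continue
        n += 1
        raw_counts[p.mod_residue] += 1
        flank = [
            p.peptide[p.mod_pos - 1 + off]
            for off in FLANK_OFFSETS
            if 1 <= p.mod_pos + off <= len(p.peptide)
        ]
        if flank:
            for a in set(flank):
                bg_sum[a] += flank.count(a) / len(flank)
    if n == 0:
        zero = {a: 0.0 for a in AMINO_ACIDS}
        return zero, dict(zero), dict(zero), 0
    raw = {a: 100.0 * raw_counts[a] / n for a in AMINO_ACIDS}
    background = {a: 100.0 * bg_sum[a] / n for a in AMINO_ACIDS}
    corrected = {a: raw[a] - background[a] for a in AMINO_ACIDS}
    return raw, background, corrected, n


def quintile_profile(peak_psms: list[PSMRecord]) -> np.ndarray:
    """Frequencies (% of modified peak PSMs) per sequence quintile 1..5."""
    counts = np.zeros(5)
    for p in peak_psms:
        if p.mod_pos is None:
            continue
        counts[quintile_of(p.mod_pos, len(p.peptide)) - 1] += 1
    total = counts.sum()
    return 100.0 * counts / total if total else counts


def classify_origin(
    peak_psms: list[PSMRecord],
    q1_threshold: float = ARTEFACT_Q1_THRESHOLD,
    min_psms: int = MIN_PSMS_FOR_CALL,
    min_internal: int = MIN_INTERNAL_PSMS,
) -> str:
    """Call a peak artefactual, biological or unknown.

    Artefactual: the shift falls in the first sequence quintile more
    than ``q1_threshold`` % of the time, judged only on PSMs whose
    peptide does not start the protein (peptide_start > 1) — a shift
    concentrated on protein N-termini (e.g. Met loss + acetylation) is
    biological, not a bench artefact.  Below ``min_psms`` modified PSMs
    the call is "unknown".
    """
    modified = [p for p in peak_psms if p.mod_pos is not None]
    if len(modified) < min_psms:
        return "unknown"
    internal = [p for p in modified if p.peptide_start > 1]
    if len(internal) >= min_internal:
        q1 = quintile_profile(internal)[0]
        if q1 > q1_threshold:
            return "artefactual"
    return "biological"


def profile_peak(peak_id: int, peak_psms: list[PSMRecord]) -> SpecificityProfile:
    """Full specificity profile plus origin call for one peak."""
    raw, background, corrected, n = residue_profile(peak_psms)
    return SpecificityProfile(
        peak_id=peak_id,
        n_psms=n,
        raw=raw,
        background=background,
        corrected=corrected,
        quintiles=quintile_profile(peak_psms),
        origin=classify_origin(peak_psms),
    )


def specificity_matrix(profiles: list[SpecificityProfile]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Heatmap-ready exports: (peaks x residues corrected scores,
    peaks x quintiles frequencies)."""
    idx = [p.peak_id for p in profiles]
    residues = pd.DataFrame(
        [[p.corrected[a] for a in AMINO_ACIDS] for p in profiles],
        index=idx, columns=list(AMINO_ACIDS),
    )
    quintiles = pd.DataFrame(
        [p.quintiles for p in profiles],
        index=idx, columns=[f"Q{i}" for i in range(1, 6)],
    )
    residues.index.name = quintiles.index.name = "peak_id"
    return residues, quintiles
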