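"""Aggregation of modified peptides into modified protein sites (qdna).

All peptidoforms that place the same delta-mass peak (d) on the same
residue (a) at the same protein position (n) of the same protein (q) —
for example the full tryptic peptide and its missed-cleavage partials —
are integrated into one quantitation element, written qdna.  The same
protein position carrying two different delta masses yields two
distinct elements.

Charge-switching Lys modifications (glycerophosphorylation, +167.98 Da)
block tryptic cleavage at the modified residue, so a genuine pgK
peptide must be a partial-digestion product: PSMs whose modified Lys is
the peptide C-terminus are contradictory and are removed by
``partial_digestion_filter``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PSMRecord, ProteinDB

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class SiteKey:
    """Identity of a modified protein site: protein q, peak d, position
    n (1-based, protein coordinates), residue type a."""

    q: str
    d: int  # delta-mass peak id
    n: int
    a: str

    def label(self) -> str:
        return f"{self.q}:{self.a}{self.n}:d{self.d}"


@dataclass
class SiteRecord:
    """One qdna element with its contributing PSMs and per-sample counts."""

    key: SiteKey
    psm_indices: list[int] = field(default_factory=list)
    sample_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.sample_counts.values())


def map_to_sites(
    psms: list[PSMRecord],
    proteindb: ProteinDB,
    peak_assignment: np.ndarray,
    keep: np.ndarray | None = None,
    isotope_parent: dict[int, int] | None = None,
) -> tuple[list[SiteRecord], list[tuple[int, str]]]:
    """Integrate modified PSMs into qdna SiteRecords.

    Only modified, peak-assigned, non-decoy PSMs (optionally restricted
    to the FDR-passing mask ``keep``) contribute.  ``isotope_parent``
    optionally remaps satellite peak ids onto their parent before
    grouping, merging the isotopic envelope of a modification into one
    element.  PSMs whose stated residue disagrees with the protein
    sequence at the mapped position are rejected with a reason.
    Returns (records sorted by key, rejected (index, reason) pairs).
    """
    records: dict[SiteKey, SiteRecord] = {}
    rejected: list[tuple[int, str]] = []
    for i, p in enumerate(psms):
        if p.mod_pos is None:
            continue  # unmodified: protein-level evidence only
        if keep is not None and not keep[i]:
            continue
        if p.is_decoy or proteindb.is_decoy(p.protein):
            continue
        d = int(peak_assignment[i])
        if d < 0:
            continue
        if isotope_parent:
            d = isotope_parent.get(d, d)
        n = p.peptide_start + p.mod_pos - 1
        if p.protein in proteindb:
            seq = proteindb[p.protein]
            if n > len(seq):
                rejected.append((i, "position beyond protein length"))
                continue
            if seq[n - 1] != p.mod_residue:
                rejected.append((i, "residue mismatch between peptide and protein"))
                continue
        key = SiteKey(q=p.protein, d=d, n=n, a=p.mod_residue)
        rec = records.get(key)
        if rec is None:
            rec = records[key] = SiteRecord(key)
        rec.psm_indices.append(i)
        rec.sample_counts[p.sample_id] = rec.sample_counts.get(p.sample_id, 0) + 1
    for i, reason in rejected:
        logger.warning("PSM %d rejected in site mapping: %s", i, reason)
    return [records[k] for k in sorted(records)], rejected


def partial_digestion_filter(
    site_records: list[SiteRecord],
    psms: list[PSMRecord],
    target_peaks: set[int],
) -> list[SiteRecord]:
    """Keep only partial-digestion evidence for charge-switching Lys peaks.

    For sites whose peak id is in ``target_peaks`` (pgK-like), a
    contributing PSM survives only if its modified Lys is not the
    peptide's C-terminal residue; a tryptic peptide ending at the
    modified Lys implies cleavage at a residue the modification would
    have blocked.  Records that lose all their PSMs are dropped.
    """
    out: list[SiteRecord] = []
    for rec in site_records:
        if rec.key.d not in target_peaks:
            out.append(rec)
            continue
        filtered = SiteRecord(rec.key)
        for i in rec.psm_indices:
            p = psms[i]
            if p.mod_pos == len(p.peptide) and p.peptide[p.mod_pos - 1] == "K":
                continue  # modified K at peptide C-terminus: not a partial
            filtered.psm_indices.append(i)
            filtered.sample_counts[p.sample_id] = filtered.sample_counts.get(p.sample_id, 0) + 1
        if filtered.psm_indices:
            out.append(filtered)
    return out


def site_count_table(
    site_records: list[SiteRecord],
    samples: list[str],
    peak_apex: dict[int, float] | None = None,
) -> pd.DataFrame:
    """qdna x samples raw-count table (plus key columns and total)."""
    rows = []
    for rec in site_records:
        row = {
            "q": rec.key.q,
            "a": rec.key.a,
            "n": rec.key.n,
            "d": rec.key.d,
            "apex": None if peak_apex is None else peak_apex.get(rec.key.d),
            "label": rec.key.label(),
        }
        for s in samples:
            row[s] = rec.sample_counts.get(s, 0)
        row["total"] = rec.total
        rows.append(row)
    return pd.DataFrame(rows)


def protein_count_table(
    psms: list[PSMRecord],
    proteindb: ProteinDB,
    samples: list[str],
    keep: np.ndarray | None = None,
) -> pd.DataFrame:
    """Protein (q) x samples PSM-count table over all non-decoy PSMs,
    modified or not."""
    counts: dict[str, dict[str, int]] = {}
    for i, p in enumerate(psms):
        if keep is not None and not keep[i]:
            continue
        if p.is_decoy or proteindb.is_decoy(p.protein):
            continue
        c = counts.setdefault(p.protein, {})
        c[p.sample_id] = c.get(p.sample_id, 0) + 1
    rows = []
    for q in sorted(counts):
        row = {"q": q}
        for s in samples:
            row[s] = counts[q].get(s, 0)
        row["total"] = sum(counts[q].values())
        rows.append(row)
    return pd.DataFrame(rows)
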