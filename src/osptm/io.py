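"""Reading and writing the pipeline's external formats.

The pipeline consumes three kinds of input: a tab-delimited PSM table as
emitted by an open-search engine (one row per peptide-spectrum match),
a protein database in FASTA with a decoy-prefix convention, and a
modification catalog (UNIMOD-like) as a delimited text file.  All
coordinates are 1-based and inclusive, both within peptides and within
proteins, matching the field's site notation (e.g. K343).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Mass of a single C13-vs-C12 neutron substitution (Da); the spacing of
#: the isotopic envelope of a precursor.
ISOTOPE_SPACING = 1.003355

DEFAULT_DECOY_PREFIX = "rev_"

#: Columns a PSM table must provide (after dialect renaming).
PSM_COLUMNS = [
    "sample_id",
    "scan_id",
    "peptide",
    "protein",
    "peptide_start",
    "delta_mass",
    "mod_pos",
    "mod_residue",
    "score",
    "is_decoy",
    "missed_cleavages",
]


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match from an open search.

    ``delta_mass`` is the experimental precursor mass minus the
    theoretical mass of the unmodified peptide candidate; ``mod_pos`` is
    the engine's best-scoring placement of that mass shift within the
    peptide (1-based), or ``None`` for unmodified PSMs.
    """

    sample_id: str
    scan_id: str
    peptide: str
    protein: str
    peptide_start: int
    delta_mass: float
    mod_pos: int | None
    mod_residue: str | None
    score: float
    is_decoy: bool
    missed_cleavages: int = 0

    def validate(self) -> str | None:
        """Return a rejection reason, or None if the record is well formed."""
        if not self.peptide or any(c not in AMINO_ACIDS for c in self.peptide):
            return "peptide not over the 20-letter alphabet"
        if not math.isfinite(self.delta_mass):
            return "delta_mass not finite"
        if self.mod_pos is not None:
            if not 1 <= self.mod_pos <= len(self.peptide):
                return "mod_pos outside peptide"
            if self.mod_residue != self.peptide[self.mod_pos - 1]:
                return "mod_residue does not match peptide at mod_pos"
        if self.peptide_start < 1:
            return "peptide_start must be 1-based"
        return None

    @property
    def is_modified(self) -> bool:
        return self.mod_pos is not None

    @property
    def protein_mod_pos(self) -> int | None:
        """1-based modified position in protein coordinates."""
        if self.mod_pos is None:
            return None
        return self.peptide_start + self.mod_pos - 1


@dataclass
class ProteinDB:
    """Accession -> sequence map with a decoy-prefix convention."""

    sequences: dict[str, str]
    decoy_prefix: str = DEFAULT_DECOY_PREFIX

    def __post_init__(self) -> None:
        self.sequences = {acc: seq.upper() for acc, seq in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, accession: str) -> bool:
        return accession in self.sequences

    def __getitem__(self, accession: str) -> str:
        return self.sequences[accession]

    def is_decoy(self, accession: str) -> bool:
        return accession.startswith(self.decoy_prefix)

    def targets(self) -> dict[str, str]:
        return {a: s for a, s in self.sequences.items() if not self.is_decoy(a)}

    def with_decoys(self) -> "ProteinDB":
        """Return a copy extended with reversed-sequence decoy entries."""
        out = dict(self.sequences)
        for acc, seq in self.targets().items():
            out[self.decoy_prefix + acc] = seq[::-1]
        return ProteinDB(out, decoy_prefix=self.decoy_prefix)


@dataclass(frozen=True)
class ModCatalogEntry:
    """A named modification with its monoisotopic mass and specificity.

    ``specificity`` holds one-letter residue codes and/or the terminal
    flags ``peptide-Nterm``, ``protein-Nterm``, ``Cterm``, ``any``.
    ``origin`` classifies the modification as biological, artefactual
    (introduced during sample preparation or fragmentation) or unknown.
    """

    name: str
    mono_mass: float
    specificity: frozenset[str]
    origin: str = "unknown"

    def __post_init__(self) -> None:
        if not math.isfinite(self.mono_mass):
            raise ValueError(f"{self.name}: mono_mass must be finite")
        if not self.specificity:
            raise ValueError(f"{self.name}: specificity must be non-empty")
        if self.origin not in ("biological", "artefactual", "unknown"):
            raise ValueError(f"{self.name}: bad origin {self.origin!r}")


def default_catalog() -> list[ModCatalogEntry]:
    """The built-in modification catalog.

    Masses are exact monoisotopic values; the phosphate-containing PTMs
    pgK (glycerophosphoryl-Lys), gpetE (glycerylphosphorylethanolamine-
    Glu) and fmnH (FMN-His) are carried at the two-decimal precision
    they are reported with.
    """
    e = ModCatalogEntry
    f = frozenset
    return [
        e("Phospho", 79.966331, f("STY"), "biological"),
        e("Carbamidomethyl", 57.021464, f("C"), "artefactual"),
        e("Oxidation", 15.994915, f("M"), "biological"),
        e("Acetyl-protein-Nterm", 42.010565, f({"protein-Nterm"}), "biological"),
        e("Deamidation", 0.984016, f("NQ"), "unknown"),
        e("Ammonia-loss", -17.026549, f({"C", "Q", "peptide-Nterm"}), "artefactual"),
        e("Met-loss", -131.040485, f({"protein-Nterm"}), "biological"),
        e("C13", ISOTOPE_SPACING, f({"any"}), "unknown"),
        e("Phosphoglyceryl", 167.98, f("K"), "biological"),
        e("Glycerylphosphorylethanolamine", 197.04, f("E"), "biological"),
        e("FMN", 454.08, f("H"), "biological"),
    ]


# ---------------------------------------------------------------------------
# PSM tables


def _parse_row(row: Mapping[str, object]) -> PSMRecord:
    mod_pos_raw = row["mod_pos"]
    mod_pos: int | None
    if mod_pos_raw is None or (isinstance(mod_pos_raw, float) and math.isnan(mod_pos_raw)):
        mod_pos = None
    else:
        mod_pos = int(mod_pos_raw)
        if mod_pos == 0:
            mod_pos = None
    mod_residue = row["mod_residue"] if mod_pos is not None else None
    if isinstance(mod_residue, float) and math.isnan(mod_residue):
        mod_residue = None
    return PSMRecord(
        sample_id=str(row["sample_id"]),
        scan_id=str(row["scan_id"]),
        peptide=str(row["peptide"]),
        protein=str(row["protein"]),
        peptide_start=int(row["peptide_start"]),
        delta_mass=float(row["delta_mass"]),
        mod_pos=mod_pos,
        mod_residue=None if mod_residue is None else str(mod_residue),
        score=float(row["score"]),
        is_decoy=bool(_parse_bool(row["is_decoy"])),
        missed_cleavages=int(row["missed_cleavages"]),
    )


def _parse_bool(value: object) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value)


def read_psm_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[PSMRecord], list[tuple[int, str]]]:
    """Read a tab-delimited PSM table.

    ``dialect`` maps this package's canonical column names to the names
    used in the file, adapting other open-search outputs.  Rows that
    violate the PSM invariants are rejected, not raised: the second
    element of the return value lists ``(row_index, reason)`` pairs.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mod_residue": "string"})
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table missing required columns: {missing}")
    records: list[PSMRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            rec = _parse_row(row)
        except (ValueError, TypeError) as exc:
            rejected.append((i, f"unparseable row: {exc}"))
            continue
        reason = rec.validate()
        if reason is None:
            records.append(rec)
        else:
            rejected.append((i, reason))
    for i, reason in rejected:
        logger.warning("PSM row %d rejected: %s", i, reason)
    return records, rejected


def write_psm_table(psms: Iterable[PSMRecord], path: str | Path) -> None:
    """Write PSMs as a tab-delimited table (inverse of read_psm_table)."""
    psms_to_frame(psms).to_csv(path, sep="\t", index=False)


def psms_to_frame(psms: Iterable[PSMRecord]) -> pd.DataFrame:
    """Columnar view of a PSM list (one row per PSM, canonical columns)."""
    rows = [
        {
            "sample_id": p.sample_id,
            "scan_id": p.scan_id,
            "peptide": p.peptide,
            "protein": p.protein,
            "peptide_start": p.peptide_start,
            "delta_mass": p.delta_mass,
            "mod_pos": p.mod_pos,
            "mod_residue": p.mod_residue,
            "score": p.score,
            "is_decoy": p.is_decoy,
            "missed_cleavages": p.missed_cleavages,
        }
        for p in psms
    ]
    return pd.DataFrame(rows, columns=PSM_COLUMNS)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> ProteinDB:
    """Read a protein FASTA into a ProteinDB; decoys flagged by prefix."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"duplicate accession {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if not sequences:
        raise ValueError(f"no FASTA entries in {path}")
    return ProteinDB(sequences, decoy_prefix=decoy_prefix)


def write_fasta(db: ProteinDB, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in db.sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Modification catalog


def read_catalog(path: str | Path) -> list[ModCatalogEntry]:
    """Read a tab-delimited modification catalog.

    Expected columns: name, mono_mass, specificity (comma-joined residue
    letters / terminal flags), origin.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["name", "mono_mass", "specificity", "origin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"catalog missing required columns: {missing}")
    if len(df) == 0:
        raise ValueError("catalog is empty")
    entries = []
    for row in df.to_dict("records"):
        try:
            mass = float(row["mono_mass"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric mass for {row['name']!r}") from exc
        spec = frozenset(s.strip() for s in str(row["specificity"]).split(",") if s.strip())
        entries.append(ModCatalogEntry(str(row["name"]), mass, spec, str(row["origin"])))
    return entries


def write_catalog(entries: Sequence[ModCatalogEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": [e.name for e in entries],
            "mono_mass": [repr(e.mono_mass) for e in entries],
            "specificity": [",".join(sorted(e.specificity)) for e in entries],
            "origin": [e.origin for e in entries],
        }
    )
    df.to_csv(path, sep="\t", index=False)
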