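"""Annotation of delta-mass peaks against a modification catalog.

Beyond direct catalog lookup, unknown mass shifts are decomposed into
composites: sums of two or more catalog masses (gains and losses may
mix, e.g. phospho + deamidation = 80.95 Da, or Met loss + N-terminal
acetyl + phospho = -9.06 Da), optionally plus one or more C13 isotope
spacings, since the isotopic envelope of a precursor displaces the
apparent shift by ~1.003 Da per C13.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .deltamass import DeltaMassPeak
from .io import ISOTOPE_SPACING, ModCatalogEntry


@dataclass(frozen=True)
class Annotation:
    """A single-entry match of a peak apex to a catalog mass."""

    entry: ModCatalogEntry
    error: float  # apex - mono_mass, Da


@dataclass(frozen=True)
class Composite:
    """A multiset of catalog entries plus k isotope offsets matching a mass."""

    entries: tuple[ModCatalogEntry, ...]
    n_isotopes: int
    mass: float
    error: float  # target - mass, Da

    @property
    def n_components(self) -> int:
        return len(self.entries) + self.n_isotopes

    def describe(self) -> str:
        parts = [e.name for e in self.entries]
        if self.n_isotopes:
            parts.append(f"{self.n_isotopes}xC13")
        return "+".join(parts)


def annotate_peak(
    peak: DeltaMassPeak | float,
    catalog: list[ModCatalogEntry],
    tol: float = 0.01,
) -> list[Annotation]:
    """Catalog entries within ``tol`` Da of the peak apex, best first.

    An empty list means the shift is unknown to the catalog.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    apex = peak if isinstance(peak, float) else peak.apex
    hits = [
        Annotation(e, apex - e.mono_mass)
        for e in catalog
        if abs(apex - e.mono_mass) <= tol
    ]
    hits.sort(key=lambda a: (abs(a.error), a.entry.name))
    return hits


def decompose_composite(
    target: float,
    catalog: list[ModCatalogEntry],
    max_terms: int = 3,
    tol: float = 0.005,
    max_isotopes: int = 3,
    max_combinations: int = 2_000_000,
) -> list[Composite]:
    """All multisets of <= max_terms catalog entries (plus up to
    ``max_isotopes`` C13 spacings) whose summed mass is within ``tol``
    of ``target``.

    Exhaustive over the combination space; ranked by |error|, then by
    fewer components, then by name for determinism.  Raises if the
    combination count exceeds ``max_combinations``.
    """
    if max_terms < 1:
        raise ValueError("max_terms must be >= 1")
    if not catalog:
        raise ValueError("catalog is empty")
    n = len(catalog)
    total = sum(math.comb(n + t - 1, t) for t in range(1, max_terms + 1))
    total *= max_isotopes + 1
    if total > max_combinations:
        raise ValueError(
            f"{total} candidate combinations exceed the cap "
            f"({max_combinations}); reduce max_terms or the catalog"
        )
    ordered = sorted(catalog, key=lambda e: e.name)
    out: list[Composite] = []
    for t in range(1, max_terms + 1):
        for combo in itertools.combinations_with_replacement(ordered, t):
            base = sum(e.mono_mass for e in combo)
            for k in range(max_isotopes + 1):
                mass = base + k * ISOTOPE_SPACING
                err = target - mass
                if abs(err) <= tol:
                    out.append(Composite(combo, k, mass, err))
    out.sort(
        key=lambda c: (abs(c.error), c.n_components, tuple(e.name for e in c.entries), c.n_isotopes)
    )
    return out


def collapse_isotopes(
    peaks: list[DeltaMassPeak],
    spacing: float = ISOTOPE_SPACING,
    tol: float = 0.01,
    max_k: int = 3,
) -> dict[int, int]:
    """Map isotope-satellite peaks onto their parent peak.

    Peak B is a satellite of peak A iff apex_B sits k spacings above
    apex_A (k in 1..max_k, within ``tol``) and A carries more PSMs than
    B.  When several parents qualify, the smallest mass error wins.
    The parent relation strictly decreases PSM count, so chains cannot
    form cycles.
    """
    mapping: dict[int, int] = {}
    for b in peaks:
        best: tuple[float, int] | None = None
        for a in peaks:
            if a.peak_id == b.peak_id or a.psm_count <= b.psm_count:
                continue
            for k in range(1, max_k + 1):
                err = abs(b.apex - a.apex - k * spacing)
                if err <= tol and (best is None or err < best[0]):
                    best = (err, a.peak_id)
        if best is not None:
            mapping[b.peak_id] = best[1]
    return mapping
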