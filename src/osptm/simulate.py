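"""Synthetic open-search PSM datasets with known ground truth.

The generator stands in for the spectral search: it emits a PSM table
with the statistical structure the downstream analysis assumes, so that
every stage — peak detection, FDR control, artefact classification,
site quantitation and response clustering — can be validated against a
known truth.

What is emulated
----------------
* an in-silico proteome digested with the combined trypsin/LysC rule
  (cleavage after every K or R) allowing missed cleavages;
* modified PSMs whose delta mass is a catalog mass plus a C13 isotope
  offset plus Gaussian measurement noise, with residue-specific
  placement;
* artefactual modifications concentrated on the newly generated peptide
  N-terminus (position 1), and a protein-N-terminal biological control;
* a balanced 3-group x 3-replicate design (control / HFD3 / HFD12) with
  planted per-site log2 fold changes forming two anti-correlated
  response modules (one falling, one rising along the diet course);
* decoy PSMs and an equally sized false-target population sharing the
  decoy score distribution, so target-decoy FDR has a real operating
  point;
* a small per-sample mass-calibration offset, so recalibration has
  something to remove.

Not emulated: fragment spectra, retention time, chimeric spectra, or
intensity-based abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser

from .io import AMINO_ACIDS, ISOTOPE_SPACING, ModCatalogEntry, PSMRecord, ProteinDB, default_catalog

#: cleave after every K or R (trypsin + LysC, no proline exception)
CLEAVAGE_RULE = r"(?<=[KR])"


def digest(sequence: str, max_missed: int = 0) -> list[tuple[str, int, int]]:
    """In-silico digestion: (peptide, 1-based start, missed cleavages).

    Cleavage occurs after every K or R; products with up to
    ``max_missed`` internal cleavage sites are returned.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seen = set()
    out = []
    for start0, pep in _pyt_parser.icleave(
        sequence, CLEAVAGE_RULE, missed_cleavages=max_missed
    ):
        if (start0, pep) in seen:
            continue
        seen.add((start0, pep))
        internal = pep[:-1]
        missed = internal.count("K") + internal.count("R")
        out.append((pep, start0 + 1, missed))
    out.sort(key=lambda t: (t[1], len(t[0])))
    return out


@dataclass
class PlantedSite:
    """Ground-truth modified protein site with its abundance model."""

    site_id: int
    protein: str
    position: int  # 1-based, protein coordinates
    residue: str
    entry_name: str
    mono_mass: float
    expected: dict[str, float]  # group -> expected PSMs per sample
    lfc: dict[str, float]  # group -> planted log2 fold change vs control
    module: int | None = None  # response-module membership, if any


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    sites: list[PlantedSite]
    psm_labels: list[str]  # "true" | "false" | "decoy", aligned with PSMs
    psm_entries: list[str | None]  # generating catalog entry, aligned
    psm_site_ids: list[int | None]  # generating site, aligned
    sample_groups: dict[str, str]
    artefact_entries: list[str]
    protein_nterm_entries: list[str]
    calibration_offsets: dict[str, float]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Defaults mirror the liver MASLD time-course design: nine samples in
    three groups (healthy control, 3 and 12 weeks of high-fat diet),
    with two planted ten-site response modules of opposite sign.
    ``psm_depth`` is the expected number of PSMs per sample.
    """

    n_proteins: int = 25
    protein_length: tuple[float, float] = (360.0, 80.0)  # mean, SD (aa)
    min_protein_length: int = 80
    kr_density: float = 0.12  # combined K+R frequency
    max_missed_cleavages: int = 5
    peptide_length_range: tuple[int, int] = (7, 35)

    catalog: list[ModCatalogEntry] = field(default_factory=default_catalog)
    background_sites_per_entry: dict[str, int] = field(
        default_factory=lambda: {
            "Phospho": 12,
            "Oxidation": 8,
            "Deamidation": 8,
            "Phosphoglyceryl": 8,
            "Glycerylphosphorylethanolamine": 6,
            "FMN": 4,
        }
    )
    artefact_entries: tuple[str, ...] = ("Carbamidomethyl", "Ammonia-loss")
    protein_nterm_entries: tuple[str, ...] = ("Acetyl-protein-Nterm",)

    groups: tuple[str, ...] = ("control", "HFD3", "HFD12")
    replicates: int = 3

    # planted response modules: (entry, log2FC at final group); the
    # intermediate group gets half the effect, controls none
    n_module_sites: int = 10
    module_plan: tuple[tuple[str, float], ...] = (
        ("Phosphoglyceryl", -1.0),
        ("Phospho", +1.0),
    )
    planted_psms_per_sample: float = 50.0  # expected PSMs/sample, control
    background_abundance: tuple[float, float] = (8.0, 0.6)  # lognormal mean PSMs, sigma
    planted_effects: list[PlantedSite] | None = None  # explicit override

    # modified sites get absolute expected rates; the unmodified bulk of
    # each sample absorbs the remaining depth, so protein-level counts
    # are dominated by unmodified peptides as in real data
    psm_depth: float = 12000.0
    decoy_fraction: float = 0.15
    false_target_fraction: float = 0.15
    artefact_fraction: float = 0.08  # of true-target PSMs, split per entry
    protein_nterm_fraction: float = 0.02  # of true-target PSMs

    noise_sd_da: float = 0.003
    calibration_offset_sd: float = 0.001
    isotope_probs: tuple[float, ...] = (0.82, 0.13, 0.05)  # k = 0, 1, 2
    nb_dispersion: float | None = None  # None = Poisson limit

    target_score_mean: float = 3.5
    decoy_score_mean: float = 0.0
    score_sd: float = 1.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("decoy_fraction", "false_target_fraction",
                     "artefact_fraction", "protein_nterm_fraction", "kr_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.psm_depth <= 0:
            raise ValueError("psm_depth must be positive")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if abs(sum(self.isotope_probs) - 1.0) > 1e-9:
            raise ValueError("isotope_probs must sum to 1")
        if self.decoy_fraction + self.false_target_fraction >= 1.0:
            raise ValueError("decoy + false-target fractions must leave room for targets")

    @property
    def samples(self) -> list[tuple[str, str]]:
        """Ordered (sample_id, group) pairs of the balanced design."""
        return [
            (f"{g}_{r + 1}", g)
            for g in self.groups
            for r in range(self.replicates)
        ]

    def entry(self, name: str) -> ModCatalogEntry:
        for e in self.catalog:
            if e.name == name:
                return e
        raise KeyError(f"catalog entry {name!r} not found")


def planted_response_matrix(
    seed: int,
    module_sizes: tuple[int, int] = (15, 12),
    n_background: int = 23,
    noise_sd: float = 0.2,
    groups: tuple[str, ...] = ("control", "HFD3", "HFD12"),
    replicates: int = 3,
    effect: float = 1.0,
) -> tuple["pd.DataFrame", dict[int, set[str]]]:
    """Site-profile matrix with two planted anti-correlated response modules.

    A direct construction at the quantitation level (log2-ratio scale):
    module 0 falls linearly along the group course to ``-effect``,
    module 1 rises to ``+effect``; background sites are flat.  All
    profiles carry iid Gaussian noise of SD ``noise_sd`` (log2 units,
    the spectral-count noise of an abundant site).  Module and
    background proportions are scaled down from the reported response
    clusters, which together hold a large share of the network sites.
    Returns (sites x samples DataFrame, {module index -> member labels}).
    """
    rng = np.random.default_rng(seed)
    steps = np.linspace(0.0, 1.0, len(groups))
    pattern = np.repeat(steps, replicates)
    columns = [f"{g}_{r + 1}" for g in groups for r in range(replicates)]
    rows, labels = [], []
    truth: dict[int, set[str]] = {0: set(), 1: set()}
    k = 0
    for mi, sign in ((0, -1.0), (1, +1.0)):
        for _ in range(module_sizes[mi]):
            rows.append(sign * effect * pattern + rng.normal(0.0, noise_sd, pattern.size))
            labels.append(f"site{k:03d}")
            truth[mi].add(labels[-1])
            k += 1
    for _ in range(n_background):
        rows.append(rng.normal(0.0, noise_sd, pattern.size))
        labels.append(f"site{k:03d}")
        k += 1
    return pd.DataFrame(rows, index=labels, columns=columns), truth


def generate_proteome(config: SimulationConfig, rng: np.random.Generator | None = None) -> ProteinDB:
    """Random proteome over the 20-letter alphabet with tunable K/R density.

    Every protein starts with Met; lengths are Gaussian, clipped below.
    Deterministic under the config seed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    letters = np.array(list(AMINO_ACIDS))
    probs = np.full(20, (1.0 - config.kr_density) / 18.0)
    for res in "KR":
        probs[AMINO_ACIDS.index(res)] = config.kr_density / 2.0
    mean, sd = config.protein_length
    sequences: dict[str, str] = {}
    for i in range(config.n_proteins):
        length = max(config.min_protein_length, int(round(rng.normal(mean, sd))))
        body = rng.choice(letters, size=length - 1, p=probs)
        sequences[f"PROT{i:04d}"] = "M" + "".join(body)
    return ProteinDB(sequences)


# ---------------------------------------------------------------------------
# internal helpers


@dataclass(frozen=True)
class _PoolEntry:
    protein: str
    peptide: str
    start: int
    missed: int


def _build_pool(db: ProteinDB, config: SimulationConfig, accessions: Sequence[str]) -> list[_PoolEntry]:
    lo, hi = config.peptide_length_range
    pool = []
    for acc in accessions:
        for pep, start, missed in digest(db[acc], config.max_missed_cleavages):
            if lo <= len(pep) <= hi:
                pool.append(_PoolEntry(acc, pep, start, missed))
    return pool


def _covering(pool_by_protein: dict[str, list[_PoolEntry]], protein: str, pos: int,
              internal_only: bool) -> list[_PoolEntry]:
    """Peptides covering protein position ``pos``; optionally only those
    where the position is not the peptide C-terminus (partial-digestion
    products, required for charge-switching Lys modifications)."""
    out = []
    for e in pool_by_protein.get(protein, []):
        if e.start <= pos <= e.start + len(e.peptide) - 1:
            if internal_only and pos == e.start + len(e.peptide) - 1:
                continue
            out.append(e)
    return out


def _plan_sites(config: SimulationConfig, db: ProteinDB,
                pool_by_protein: dict[str, list[_PoolEntry]],
                rng: np.random.Generator) -> list[PlantedSite]:
    """Choose ground-truth modified sites: response modules first, then
    flat background sites, all with at least one covering peptide."""
    if config.planted_effects is not None:
        for s in config.planted_effects:
            if db[s.protein][s.position - 1] != s.residue:
                raise ValueError(
                    f"planted site {s.protein}:{s.position} expects {s.residue}, "
                    f"proteome has {db[s.protein][s.position - 1]}"
                )
        return list(config.planted_effects)

    used: set[tuple[str, int]] = set()
    sites: list[PlantedSite] = []
    site_id = 0

    def candidates(entry: ModCatalogEntry) -> list[tuple[str, int, str]]:
        residues = {r for r in entry.specificity if len(r) == 1}
        internal_only = "K" in residues  # charge-switching Lys: partial digestion
        cands = []
        for acc in sorted(db.targets()):
            seq = db[acc]
            for pos0, res in enumerate(seq):
                if res in residues and (acc, pos0 + 1) not in used:
                    if _covering(pool_by_protein, acc, pos0 + 1, internal_only):
                        cands.append((acc, pos0 + 1, res))
        return cands

    # response modules
    final_group = config.groups[-1]
    mid_groups = config.groups[1:-1]
    for module_idx, (entry_name, lfc_final) in enumerate(config.module_plan):
        entry = config.entry(entry_name)
        cands = candidates(entry)
        if len(cands) < config.n_module_sites:
            raise ValueError(f"not enough candidate sites for module entry {entry_name}")
        chosen = rng.choice(len(cands), size=config.n_module_sites, replace=False)
        for c in chosen:
            acc, pos, res = cands[c]
            used.add((acc, pos))
            lfc = {config.groups[0]: 0.0, final_group: lfc_final}
            for k, g in enumerate(mid_groups, start=1):
                lfc[g] = lfc_final * k / (len(mid_groups) + 1)
            sites.append(PlantedSite(
                site_id, acc, pos, res, entry.name, entry.mono_mass,
                expected={}, lfc=lfc, module=module_idx,
            ))
            site_id += 1

    # flat background sites
    for entry_name, n_sites in config.background_sites_per_entry.items():
        entry = config.entry(entry_name)
        cands = candidates(entry)
        n_take = min(n_sites, len(cands))
        chosen = rng.choice(len(cands), size=n_take, replace=False)
        for c in chosen:
            acc, pos, res = cands[c]
            used.add((acc, pos))
            sites.append(PlantedSite(
                site_id, acc, pos, res, entry.name, entry.mono_mass,
                expected={}, lfc={g: 0.0 for g in config.groups}, module=None,
            ))
            site_id += 1
    return sites


def _draw_count(rng: np.random.Generator, lam: float, dispersion: float | None) -> int:
    if lam <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(lam))
    # negative binomial with mean lam, variance lam + lam^2/dispersion
    p = dispersion / (dispersion + lam)
    return int(rng.negative_binomial(dispersion, p))


def simulate_psm_dataset(config: SimulationConfig) -> tuple[list[PSMRecord], GroundTruth]:
    """Draw a full synthetic PSM dataset plus its ground truth.

    Deterministic under ``config.seed``: the same config yields a
    byte-identical PSM table.
    """
    rng = np.random.default_rng(config.seed)
    db = generate_proteome(config, rng)
    target_accs = sorted(db.targets())
    pool = _build_pool(db, config, target_accs)
    pool_by_protein: dict[str, list[_PoolEntry]] = {}
    for e in pool:
        pool_by_protein.setdefault(e.protein, []).append(e)
    decoy_db = db.with_decoys()
    decoy_accs = [a for a in sorted(decoy_db.sequences) if decoy_db.is_decoy(a)]
    decoy_pool = _build_pool(decoy_db, config, decoy_accs)
    nterm_pool = [e for e in pool if e.start == 1]

    sites = _plan_sites(config, db, pool_by_protein, rng)

    # per-sample expected rates; sites get absolute rates, the
    # unmodified bulk absorbs whatever depth remains
    depth = config.psm_depth
    decoy_rate = depth * config.decoy_fraction
    ft_rate = depth * config.false_target_fraction
    true_rate = depth - decoy_rate - ft_rate
    art_total = true_rate * config.artefact_fraction
    art_rate = art_total / max(1, len(config.artefact_entries))
    nterm_rate = true_rate * config.protein_nterm_fraction

    bg_mean, bg_sigma = config.background_abundance
    weights = np.array([
        config.planted_psms_per_sample if s.module is not None
        else float(rng.lognormal(np.log(bg_mean), bg_sigma))
        for s in sites
    ])
    unmod_rate = true_rate - art_total - nterm_rate - float(weights.sum())
    if unmod_rate <= 0:
        raise ValueError(
            "psm_depth too small for the configured site abundances; "
            "no depth left for the unmodified population"
        )
    for s, w in zip(sites, weights):
        s.expected = {g: w * 2.0 ** s.lfc[g] for g in config.groups}

    site_cover = [
        _covering(pool_by_protein, s.protein, s.position,
                  internal_only=(s.residue == "K"))
        for s in sites
    ]

    # mass-category mixture shared by false targets and decoys: they are
    # wrong answers drawn across the same delta-mass landscape
    cat_masses = [0.0]
    cat_weights = [unmod_rate]
    for entry_name in config.artefact_entries:
        cat_masses.append(config.entry(entry_name).mono_mass)
        cat_weights.append(art_rate)
    for entry_name in config.protein_nterm_entries:
        cat_masses.append(config.entry(entry_name).mono_mass)
        cat_weights.append(nterm_rate)
    seen: dict[str, int] = {}
    for s in sites:
        if s.entry_name in seen:
            cat_weights[seen[s.entry_name]] += s.expected[config.groups[0]]
        else:
            seen[s.entry_name] = len(cat_masses)
            cat_masses.append(s.mono_mass)
            cat_weights.append(s.expected[config.groups[0]])
    cat_masses_arr = np.array(cat_masses)
    cat_probs = np.array(cat_weights) / np.sum(cat_weights)
    iso_k = np.arange(len(config.isotope_probs))
    iso_p = np.array(config.isotope_probs)

    psms: list[PSMRecord] = []
    labels: list[str] = []
    entries: list[str | None] = []
    site_ids: list[int | None] = []
    cal_offsets: dict[str, float] = {}

    def noise() -> float:
        return float(rng.normal(0.0, config.noise_sd_da))

    def iso_shift() -> float:
        return float(rng.choice(iso_k, p=iso_p)) * ISOTOPE_SPACING

    for sample_id, group in config.samples:
        offset = float(rng.normal(0.0, config.calibration_offset_sd))
        cal_offsets[sample_id] = offset
        scan = 0

        def emit(pep_entry: _PoolEntry, dm: float, mod_pos: int | None,
                 score: float, is_decoy: bool, label: str,
                 entry_name: str | None, site_id: int | None) -> None:
            nonlocal scan
            psms.append(PSMRecord(
                sample_id=sample_id,
                scan_id=f"{sample_id}_scan{scan:06d}",
                peptide=pep_entry.peptide,
                protein=pep_entry.protein,
                peptide_start=pep_entry.start,
                delta_mass=dm + offset,
                mod_pos=mod_pos,
                mod_residue=None if mod_pos is None else pep_entry.peptide[mod_pos - 1],
                score=score,
                is_decoy=is_decoy,
                missed_cleavages=pep_entry.missed,
            ))
            labels.append(label)
            entries.append(entry_name)
            site_ids.append(site_id)
            scan += 1

        def target_score() -> float:
            return float(rng.normal(config.target_score_mean, config.score_sd))

        def decoy_score() -> float:
            return float(rng.normal(config.decoy_score_mean, config.score_sd))

        # ground-truth modified sites
        for s, cover in zip(sites, site_cover):
            n = _draw_count(rng, s.expected[group], config.nb_dispersion)
            for _ in range(n):
                pe = cover[int(rng.integers(len(cover)))]
                mod_pos = s.position - pe.start + 1
                dm = s.mono_mass + iso_shift() + noise()
                emit(pe, dm, mod_pos, target_score(), False, "true", s.entry_name, s.site_id)

        # unmodified PSMs (isotope satellites around zero)
        for _ in range(_draw_count(rng, unmod_rate, config.nb_dispersion)):
            pe = pool[int(rng.integers(len(pool)))]
            emit(pe, iso_shift() + noise(), None, target_score(), False, "true", None, None)

        # artefactual modifications: forced to the peptide N-terminus
        for entry_name in config.artefact_entries:
            entry = config.entry(entry_name)
            for _ in range(_draw_count(rng, art_rate, config.nb_dispersion)):
                pe = pool[int(rng.integers(len(pool)))]
                dm = entry.mono_mass + iso_shift() + noise()
                emit(pe, dm, 1, target_score(), False, "true", entry_name, None)

        # protein-N-terminal biological control
        for entry_name in config.protein_nterm_entries:
            entry = config.entry(entry_name)
            for _ in range(_draw_count(rng, nterm_rate, config.nb_dispersion)):
                pe = nterm_pool[int(rng.integers(len(nterm_pool)))]
                dm = entry.mono_mass + iso_shift() + noise()
                emit(pe, dm, 1, target_score(), False, "true", entry_name, None)

        # false targets: wrong matches, decoy-like scores, target proteins
        for _ in range(_draw_count(rng, ft_rate, config.nb_dispersion)):
            pe = pool[int(rng.integers(len(pool)))]
            mass = float(cat_masses_arr[int(rng.choice(len(cat_masses_arr), p=cat_probs))])
            mod_pos = None if mass == 0.0 else int(rng.integers(1, len(pe.peptide) + 1))
            dm = mass + iso_shift() + noise()
            emit(pe, dm, mod_pos, decoy_score(), False, "false", None, None)

        # decoys
        for _ in range(_draw_count(rng, decoy_rate, config.nb_dispersion)):
            pe = decoy_pool[int(rng.integers(len(decoy_pool)))]
            mass = float(cat_masses_arr[int(rng.choice(len(cat_masses_arr), p=cat_probs))])
            mod_pos = None if mass == 0.0 else int(rng.integers(1, len(pe.peptide) + 1))
            dm = mass + iso_shift() + noise()
            emit(pe, dm, mod_pos, decoy_score(), True, "decoy", None, None)

    truth = GroundTruth(
        sites=sites,
        psm_labels=labels,
        psm_entries=entries,
        psm_site_ids=site_ids,
        sample_groups=dict(config.samples),
        artefact_entries=list(config.artefact_entries),
        protein_nterm_entries=list(config.protein_nterm_entries),
        calibration_offsets=cal_offsets,
    )
    return psms, truth
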