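"""End-to-end orchestration of the open-search downstream analysis.

From a PSM table and protein database to: recalibrated delta masses,
modelled delta-mass peaks with catalog/composite annotation and origin
calls, qdna site records, standardized quantitation (Zq, Zq_qdna) and
correlation-network response clusters.  Each stage is also available
individually from its own module; this wrapper fixes the default
parameterization and the order of operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotation as ann
from . import deltamass as dmod
from . import netstats, quant, sites, specificity
from .io import ModCatalogEntry, PSMRecord, ProteinDB, default_catalog


@dataclass
class AnalysisParams:
    """Tunable parameters of the full pipeline (defaults throughout)."""

    fdr_threshold: float = 0.01
    peak_bandwidth: float = 0.005  # Da
    peak_min_psm: int = 5
    annotation_tol: float = 0.01  # Da
    isotope_tol: float = 0.01  # Da
    charge_switch_entries: tuple[str, ...] = ("Phosphoglyceryl",)
    merge_isotope_sites: bool = False
    pseudocount: float = 0.5
    min_total: int = 15
    require_all_samples: bool = True
    r_min: float = 0.5
    cluster_min_size: int = 5
    cluster_penalty: float = 2.0
    cluster_overlap: float = 0.8
    cluster_min_density: float = 0.3
    control_group: str | None = None


@dataclass
class AnalysisResult:
    psms: list[PSMRecord]  # recalibrated
    corrections: dict[str, float]
    peaks: list[dmod.DeltaMassPeak]
    assignment: np.ndarray
    fdr: dmod.FDRResult
    keep: np.ndarray  # FDR-passing non-decoy PSMs
    annotations: dict[int, list[ann.Annotation]]
    isotope_parent: dict[int, int]
    profiles: list[specificity.SpecificityProfile]
    site_records: list[sites.SiteRecord]
    site_rejections: list[tuple[int, str]]
    protein_counts: pd.DataFrame
    site_counts: pd.DataFrame
    protein_matrix: quant.QuantMatrix | None
    site_matrix: quant.QuantMatrix | None
    zq_qdna: pd.DataFrame | None
    graph: object | None
    clusters: list[netstats.ClusterResult] = field(default_factory=list)
    cluster_ks: list[tuple[float, float]] = field(default_factory=list)
    group_means: pd.DataFrame | None = None


def analyze(
    psms: list[PSMRecord],
    proteindb: ProteinDB,
    catalog: list[ModCatalogEntry] | None = None,
    design: dict[str, str] | None = None,
    params: AnalysisParams | None = None,
) -> AnalysisResult:
    """Run the full downstream analysis on an open-search PSM table.

    ``design`` maps sample ids to group labels; when given (with
    ``params.control_group``) the response-clustering stage computes
    group averages, contrasts and KS statistics.
    """
    catalog = default_catalog() if catalog is None else catalog
    params = params or AnalysisParams()
    samples = sorted({p.sample_id for p in psms})

    psms, corrections = dmod.recalibrate(psms)
    peaks = dmod.detect_peaks(psms, bandwidth=params.peak_bandwidth, min_psm=params.peak_min_psm)
    assignment = dmod.assign_to_peaks(psms, peaks)
    fdr = dmod.fdr_filter(psms, peaks, threshold=params.fdr_threshold, peak_assignment=assignment)
    is_decoy = np.array([p.is_decoy for p in psms])
    keep = fdr.passed & ~is_decoy

    annotations = {
        p.peak_id: ann.annotate_peak(p, catalog, tol=params.annotation_tol) for p in peaks
    }
    isotope_parent = ann.collapse_isotopes(peaks, tol=params.isotope_tol)

    profiles = []
    for p in peaks:
        members = [psms[i] for i in np.flatnonzero((assignment == p.peak_id) & keep)]
        profiles.append(specificity.profile_peak(p.peak_id, members))

    # peaks carrying a charge-switching Lys modification (directly or as
    # an isotope satellite of one) demand partial-digestion evidence
    pgk_root = {
        pid for pid, hits in annotations.items()
        if hits and hits[0].entry.name in params.charge_switch_entries
    }
    pgk_peaks = {
        p.peak_id for p in peaks
        if p.peak_id in pgk_root or isotope_parent.get(p.peak_id) in pgk_root
    }

    site_records, site_rejections = sites.map_to_sites(
        psms, proteindb, assignment, keep=keep,
        isotope_parent=isotope_parent if params.merge_isotope_sites else None,
    )
    site_records = sites.partial_digestion_filter(site_records, psms, pgk_peaks)

    protein_counts = sites.protein_count_table(psms, proteindb, samples, keep=keep)
    apex = {p.peak_id: p.apex for p in peaks}
    site_counts = sites.site_count_table(site_records, samples, peak_apex=apex)

    protein_matrix = site_matrix = None
    zq_qdna = None
    graph = None
    clusters: list[netstats.ClusterResult] = []
    cluster_ks: list[tuple[float, float]] = []
    group_means = None

    if len(protein_counts) and len(site_counts):
        kept_per_sample: dict[str, int] = {s: 0 for s in samples}
        for i in np.flatnonzero(keep):
            kept_per_sample[psms[i].sample_id] += 1
        totals = pd.Series(kept_per_sample, dtype=float).reindex(samples)
        prot = protein_counts.set_index("q")[samples]
        prot = quant.filter_quantifiable(prot, params.min_total, params.require_all_samples)
        site = site_counts.set_index("label")[samples]
        site = quant.filter_quantifiable(site, params.min_total, params.require_all_samples)
        if len(prot) >= 3 and len(site) >= 3:
            protein_matrix = quant.quantify(prot, params.pseudocount, totals=totals)
            site_matrix = quant.quantify(site, params.pseudocount, totals=totals)
            site_protein = site_counts.set_index("label")["q"].loc[site.index]
            zq_qdna = quant.protein_normalize(site_matrix, protein_matrix, site_protein)

            graph = netstats.correlation_network(zq_qdna, r_min=params.r_min)
            clusters = netstats.cluster_cohesive(
                graph,
                min_size=params.cluster_min_size,
                penalty=params.cluster_penalty,
                overlap=params.cluster_overlap,
                min_density=params.cluster_min_density,
            )
            if design:
                control = params.control_group or sorted(set(design.values()))[0]
                group_means = netstats.group_average(zq_qdna, design, control=control)
                final = [g for g in group_means.columns if g.endswith(f"_vs_{control}")]
                if final:
                    contrast = group_means[final[-1]]
                    for c in clusters:
                        members = [m for m in c.members if m in contrast.index]
                        c.group_means = group_means.loc[members]
                        if len(members) >= 2:
                            cluster_ks.append(netstats.ks_two_sample(
                                contrast.loc[members], contrast
                            ))
                        else:
                            cluster_ks.append((np.nan, np.nan))

    return AnalysisResult(
        psms=psms,
        corrections=corrections,
        peaks=peaks,
        assignment=assignment,
        fdr=fdr,
        keep=keep,
        annotations=annotations,
        isotope_parent=isotope_parent,
        profiles=profiles,
        site_records=site_records,
        site_rejections=site_rejections,
        protein_counts=protein_counts,
        site_counts=site_counts,
        protein_matrix=protein_matrix,
        site_matrix=site_matrix,
        zq_qdna=zq_qdna,
        graph=graph,
        clusters=clusters,
        cluster_ks=cluster_ks,
        group_means=group_means,
    )


def annotated_peak_table(result: AnalysisResult, max_composites: int = 3) -> pd.DataFrame:
    """Peak table with best annotation, composite candidates and origin."""
    rows = []
    profile_by_id = {p.peak_id: p for p in result.profiles}
    for p in result.peaks:
        hits = result.annotations.get(p.peak_id, [])
        prof = profile_by_id.get(p.peak_id)
        rows.append({
            "peak_id": p.peak_id,
            "apex": round(p.apex, 5),
            "psm_count": p.psm_count,
            "annotation": hits[0].entry.name if hits else "unknown",
            "isotope_parent": result.isotope_parent.get(p.peak_id, -1),
            "origin": prof.origin if prof else "unknown",
        })
    return pd.DataFrame(rows)
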