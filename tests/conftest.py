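"""Shared fixtures: one full-size synthetic dataset and its analysis
(session-scoped; several suites and the acceptance checks reuse them),
plus a small fast configuration for tests that re-run the generator."""

from __future__ import annotations

import pytest

from osptm.pipeline import AnalysisParams, analyze
from osptm.simulate import SimulationConfig, generate_proteome, simulate_psm_dataset

DEFAULT_SEED = 0


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A reduced-depth configuration for fast generator tests."""
    kwargs = dict(
        n_proteins=6,
        protein_length=(240.0, 40.0),
        psm_depth=800.0,
        planted_psms_per_sample=10.0,
        n_module_sites=3,
        background_sites_per_entry={"Phospho": 3, "Oxidation": 2, "Phosphoglyceryl": 2},
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def default_dataset():
    """The default study conditions: 9 samples, ~110k PSMs, planted
    response modules and artefact entries, with ground truth."""
    config = SimulationConfig(seed=DEFAULT_SEED)
    psms, truth = simulate_psm_dataset(config)
    db = generate_proteome(config).with_decoys()
    return config, psms, truth, db


@pytest.fixture(scope="session")
def default_analysis(default_dataset):
    """Full pipeline result on the default dataset (isotope satellites
    merged into their parent sites for quantitation)."""
    config, psms, truth, db = default_dataset
    params = AnalysisParams(control_group="control", merge_isotope_sites=True)
    return analyze(psms, db, design=truth.sample_groups, params=params)


def truth_site_label(site, result) -> str:
    """qdna label of a ground-truth site under the result's peak ids."""
    apex = {p.peak_id: p.apex for p in result.peaks}
    pid = min(apex, key=lambda k: abs(apex[k] - site.mono_mass))
    return f"{site.protein}:{site.residue}{site.position}:d{pid}"
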