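"""Synthetic-data generator: digestion rule, proteome statistics,
dataset determinism and ground-truth consistency."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from osptm.io import ISOTOPE_SPACING, psms_to_frame
from osptm.simulate import (
    SimulationConfig,
    digest,
    generate_proteome,
    planted_response_matrix,
    simulate_psm_dataset,
)

from conftest import small_config


class TestDigest:
    def test_no_missed_cleavages(self):
        assert digest("AAKGGRCC", 0) == [("AAK", 1, 0), ("GGR", 4, 0), ("CC", 7, 0)]

    def test_one_missed_cleavage_adds_windows(self):
        got = set(digest("AAKGGRCC", 1))
        assert got == {
            ("AAK", 1, 0), ("GGR", 4, 0), ("CC", 7, 0),
            ("AAKGGR", 1, 1), ("GGRCC", 4, 1),
        }

    def test_no_cleavage_sites_gives_whole_sequence(self):
        assert digest("ACDEFG", 2) == [("ACDEFG", 1, 0)]

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            digest("", 0)

    @settings(deadline=None, max_examples=50)
    @given(
        seq=st.text(alphabet="ACDKRST", min_size=1, max_size=40),
        max_missed=st.integers(0, 3),
    )
    def test_products_are_consistent_windows(self, seq, max_missed):
        """Every product is a substring at its stated start, its missed-
        cleavage count matches its internal K/R content, and the
        zero-missed products concatenate back to the sequence."""
        products = digest(seq, max_missed)
        for pep, start, missed in products:
            assert seq[start - 1 : start - 1 + len(pep)] == pep
            assert missed == pep[:-1].count("K") + pep[:-1].count("R")
            assert missed <= max_missed
        full = [p for p in products if p[2] == 0]
        assert "".join(pep for pep, _, _ in sorted(full, key=lambda t: t[1])) == seq


class TestProteome:
    def test_deterministic_under_seed(self):
        cfg = small_config(seed=5)
        assert generate_proteome(cfg).sequences == generate_proteome(cfg).sequences

    def test_kr_density_is_respected(self):
        cfg = SimulationConfig(
            n_proteins=50, protein_length=(400.0, 0.0), kr_density=0.12, seed=3
        )
        db = generate_proteome(cfg)
        seq = "".join(db.sequences.values())
        density = (seq.count("K") + seq.count("R")) / len(seq)
        assert density == pytest.approx(0.12, abs=0.02)

    def test_zero_proteins_errors(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_proteins=0)


class TestDataset:
    def test_byte_identical_under_seed(self):
        cfg = small_config(seed=9)
        a, _ = simulate_psm_dataset(cfg)
        b, _ = simulate_psm_dataset(cfg)
        assert psms_to_frame(a).equals(psms_to_frame(b))

    def test_decoy_share_matches_config(self, default_dataset):
        config, psms, _, _ = default_dataset
        share = np.mean([p.is_decoy for p in psms])
        assert share == pytest.approx(config.decoy_fraction, abs=0.03)

    def test_balanced_design(self, default_dataset):
        config, psms, truth, _ = default_dataset
        groups = {}
        for s, g in truth.sample_groups.items():
            groups.setdefault(g, []).append(s)
        assert set(groups) == set(config.groups)
        assert all(len(v) == config.replicates for v in groups.values())

    def test_planted_effect_visible_in_raw_counts(self, default_dataset):
        """A +1 log2 planted effect should roughly double the emitted
        PSM count of the site in the final group versus control."""
        config, psms, truth, _ = default_dataset
        site_ids = np.array([-1 if i is None else i for i in truth.psm_site_ids])
        sample = np.array([p.sample_id for p in psms])
        groups = truth.sample_groups
        ratios = []
        for s in truth.sites:
            if s.module is None or s.lfc["HFD12"] != 1.0:
                continue
            mask = site_ids == s.site_id
            n_h = sum(int((mask & (sample == ss)).sum()) for ss in groups if groups[ss] == "HFD12")
            n_c = sum(int((mask & (sample == ss)).sum()) for ss in groups if groups[ss] == "control")
            ratios.append(n_h / n_c)
        assert len(ratios) == 10
        assert 1.6 <= np.mean(ratios) <= 2.5

    def test_psms_consistent_with_ground_truth(self, default_dataset):
        """Site-generated PSMs carry the right residue at the right
        protein position, and their delta mass sits within 4 SD of the
        catalog mass plus an integer number of isotope spacings."""
        config, psms, truth, db = default_dataset
        by_id = {s.site_id: s for s in truth.sites}
        checked = 0
        outliers = 0
        for p, sid in zip(psms, truth.psm_site_ids):
            if sid is None:
                continue
            s = by_id[sid]
            assert p.mod_residue == s.residue == db[p.protein][s.position - 1]
            assert p.peptide_start + p.mod_pos - 1 == s.position
            resid = p.delta_mass - s.mono_mass - truth.calibration_offsets[p.sample_id]
            k = round(resid / ISOTOPE_SPACING)
            assert 0 <= k <= len(config.isotope_probs) - 1
            outliers += abs(resid - k * ISOTOPE_SPACING) > 4 * config.noise_sd_da
            checked += 1
        assert checked > 1000
        # Gaussian noise: essentially everything within 4 SD of the
        # catalog mass (plus isotope offsets), allowing the expected tail
        assert outliers / checked < 1e-3

    def test_charge_switching_lys_sites_are_internal(self, default_dataset):
        """pgK-like planted PSMs never place the modified Lys at the
        peptide C-terminus (partial digestion by construction)."""
        _, psms, truth, _ = default_dataset
        by_id = {s.site_id: s for s in truth.sites}
        n = 0
        for p, sid in zip(psms, truth.psm_site_ids):
            if sid is None or by_id[sid].residue != "K":
                continue
            assert p.mod_pos < len(p.peptide)
            n += 1
        assert n > 100

    def test_artefact_psms_sit_at_peptide_nterm(self, default_dataset):
        _, psms, truth, _ = default_dataset
        art = set(truth.artefact_entries)
        n = 0
        for p, entry in zip(psms, truth.psm_entries):
            if entry in art:
                assert p.mod_pos == 1
                n += 1
        assert n > 100

    def test_inconsistent_planted_site_errors(self):
        from osptm.simulate import PlantedSite

        cfg = small_config(seed=2)
        db = generate_proteome(cfg)
        acc = sorted(db.targets())[0]
        pos = db[acc].index("K") + 1
        bad = PlantedSite(
            site_id=0, protein=acc, position=pos, residue="S",  # actually K
            entry_name="Phospho", mono_mass=79.966331,
            expected={}, lfc={g: 0.0 for g in cfg.groups},
        )
        cfg2 = small_config(seed=2, planted_effects=[bad])
        with pytest.raises(ValueError, match="expects S"):
            simulate_psm_dataset(cfg2)


class TestPlantedResponseMatrix:
    def test_shape_and_truth(self):
        m, truth = planted_response_matrix(seed=4)
        assert m.shape == (15 + 12 + 23, 9)
        assert truth[0].isdisjoint(truth[1])
        assert len(truth[0]) == 15 and len(truth[1]) == 12

    def test_modules_move_in_opposite_directions(self):
        m, truth = planted_response_matrix(seed=4)
        hfd12 = [c for c in m.columns if c.startswith("HFD12")]
        ctrl = [c for c in m.columns if c.startswith("control")]
        contrast = m[hfd12].mean(axis=1) - m[ctrl].mean(axis=1)
        assert contrast.loc[sorted(truth[0])].mean() < -0.5
        assert contrast.loc[sorted(truth[1])].mean() > 0.5
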