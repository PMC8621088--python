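"""Synthetic drug library and planted-rule DDI dataset generator."""

import numpy as np
import pytest
from rdkit import Chem
from scipy import stats

from haini.cyp_features import CYP_PANEL, encode_perpetrator, encode_victim
from haini.errors import SimulationError
from haini.synthetic_data import (
    SimulationConfig,
    generate_ddi_dataset,
    generate_drug_library,
    rule_label,
)


class TestDrugLibrary:
    def test_every_smiles_parses(self):
        drugs = generate_drug_library(SimulationConfig(n_drugs=300, seed=2))
        assert all(Chem.MolFromSmiles(d.smiles) is not None for d in drugs)

    def test_same_seed_gives_identical_library(self):
        cfg = SimulationConfig(n_drugs=50, seed=9)
        assert generate_drug_library(cfg) == generate_drug_library(cfg)

    def test_substrate_frequency_matches_probability(self):
        cfg = SimulationConfig(n_drugs=2000, seed=0)
        drugs = generate_drug_library(cfg)
        p = cfg.substrate_prob
        sd = np.sqrt(p * (1 - p) / cfg.n_drugs)
        for e in CYP_PANEL:
            freq = np.mean([e in d.cyp_profile.substrates for d in drugs])
            assert abs(freq - p) < 3 * sd

    def test_profiles_never_conflict_by_construction(self):
        drugs = generate_drug_library(SimulationConfig(n_drugs=500, seed=1))
        for d in drugs:
            assert not (d.cyp_profile.inhibitors & d.cyp_profile.inducers)


class TestDDIDataset:
    def test_noise_free_labels_follow_the_decision_table(self):
        cfg = SimulationConfig(n_drugs=60, n_pairs=400, seed=3, label_noise=0.0)
        drugs = generate_drug_library(cfg)
        dmap = {d.drug_id: d for d in drugs}
        for p in generate_ddi_dataset(drugs, cfg):
            assert p.label == rule_label(dmap[p.victim_id], dmap[p.perpetrator_id], cfg)

    def test_cyp_restricted_rule_is_function_of_interaction_vector(self):
        cfg = SimulationConfig(n_drugs=60, n_pairs=300, seed=5, label_noise=0.0,
                               rule_enzymes=("3A4",), chem_rule=False)
        drugs = generate_drug_library(cfg)
        dmap = {d.drug_id: d for d in drugs}
        i = CYP_PANEL.index("3A4")
        for p in generate_ddi_dataset(drugs, cfg):
            v = (encode_victim(dmap[p.victim_id].cyp_profile)
                 * encode_perpetrator(dmap[p.perpetrator_id].cyp_profile))[i]
            expected = {1: 4, -1: 10, 0: 13}[int(v)]  # 3A4 is panel position 10
            assert p.label == expected

    def test_same_seed_gives_identical_dataset(self):
        cfg = SimulationConfig(n_drugs=50, n_pairs=200, seed=11)
        drugs = generate_drug_library(cfg)
        assert generate_ddi_dataset(drugs, cfg) == generate_ddi_dataset(drugs, cfg)

    def test_class_sizes_decay_geometrically(self):
        """Chi-square of observed counts against the geometric profile
        (noise off: the noise mixture would flatten the tail)."""
        cfg = SimulationConfig(n_drugs=300, n_pairs=10000, seed=4, label_noise=0.0)
        drugs = generate_drug_library(cfg)
        pairs = generate_ddi_dataset(drugs, cfg)
        counts = np.array(sorted(
            np.unique([p.label for p in pairs], return_counts=True)[1]))[::-1]
        ranks = np.arange(len(counts))
        weights = cfg.class_decay ** ranks
        expected = cfg.n_pairs * weights / weights.sum()
        # pool tiny expected cells for chi-square validity
        keep = expected >= 5
        obs, exp = counts[keep].astype(float), expected[keep]
        if (~keep).any():
            obs = np.append(obs, counts[~keep].sum())
            exp = np.append(exp, expected[~keep].sum())
        chi = stats.chisquare(obs, exp)
        assert chi.pvalue > 1e-3

    def test_requesting_more_pairs_than_exist_errors(self):
        cfg = SimulationConfig(n_drugs=3, n_pairs=7, seed=0)
        drugs = generate_drug_library(cfg)
        with pytest.raises(SimulationError):
            generate_ddi_dataset(drugs, cfg)

    def test_noise_rate_is_respected(self):
        cfg = SimulationConfig(n_drugs=120, n_pairs=3000, seed=8, label_noise=0.2)
        drugs = generate_drug_library(cfg)
        dmap = {d.drug_id: d for d in drugs}
        clean = SimulationConfig(**{**cfg.__dict__, "label_noise": 0.0})
        flips = np.mean([
            p.label != rule_label(dmap[p.victim_id], dmap[p.perpetrator_id], clean)
            for p in generate_ddi_dataset(drugs, cfg)])
        # flip probability is eps * (k-1)/k
        expected = 0.2 * 18 / 19
        assert abs(flips - expected) < 3 * np.sqrt(expected * (1 - expected) / 3000)


class TestConfigValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(substrate_prob=1.2)
        with pytest.raises(ValueError):
            SimulationConfig(inhibitor_prob=0.7, inducer_prob=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(label_noise=0.6)
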