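"""Ground-truth generator: determinism, study-design fidelity, recovery metrics."""

import dataclasses
import re

import numpy as np
import pandas as pd
import pytest

from duoquant.consolidate import ConsolidationResult
from duoquant.simulate import (
    SimulationConfig,
    SyntheticTruth,
    recovery_metrics,
    simulate_evidence,
    simulate_truth,
)


class TestSimulateTruth:
    def test_entry_count_and_de_count(self):
        cfg = SimulationConfig(n_proteins=100, de_fraction=0.1, seed=1)
        truth = simulate_truth(cfg)
        assert len(truth.table) == 100
        assert truth.table["is_de"].sum() == 10

    def test_zero_de_fraction_gives_no_de_proteins(self):
        truth = simulate_truth(SimulationConfig(n_proteins=60, de_fraction=0.0, seed=2))
        assert truth.table["is_de"].sum() == 0
        assert (truth.table["true_fold_change"] == 1.0).all()

    def test_same_seed_is_identical(self):
        cfg = SimulationConfig(n_proteins=80, seed=7)
        t1, t2 = simulate_truth(cfg), simulate_truth(cfg)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        pd.testing.assert_frame_equal(t1.peptides, t2.peptides)

    def test_different_seed_differs(self):
        t1 = simulate_truth(SimulationConfig(n_proteins=80, seed=7))
        t2 = simulate_truth(SimulationConfig(n_proteins=80, seed=8))
        assert not t1.table["base_abundance"].equals(t2.table["base_abundance"])

    def test_sequences_are_valid_and_in_length_range(self):
        cfg = SimulationConfig(n_proteins=50, seed=3)
        truth = simulate_truth(cfg)
        lo, hi = cfg.seq_len_range
        for seq in truth.table["sequence"]:
            assert re.fullmatch(r"[A-Z]+", seq) and lo <= len(seq) <= hi

    def test_de_directions_roughly_balanced(self):
        truth = simulate_truth(SimulationConfig(n_proteins=1000, de_fraction=0.2, seed=4))
        ups = (truth.table["direction"] == "up").sum()
        downs = (truth.table["direction"] == "down").sum()
        assert ups + downs == 200 and min(ups, downs) >= 70

    def test_invalid_config_names_the_field(self):
        with pytest.raises(ValueError, match="de_fraction"):
            SimulationConfig(de_fraction=1.5)
        with pytest.raises(ValueError, match="n_control"):
            SimulationConfig(n_control=1)


class TestSimulateEvidence:
    def test_no_dropout_no_de_detects_every_protein_everywhere(self):
        cfg = SimulationConfig(n_proteins=40, de_fraction=0.0, dropout=False, seed=11)
        truth = simulate_truth(cfg)
        ev_a, _, design, _ = simulate_evidence(truth, cfg)
        with_peptides = set(truth.peptides["protein"])
        seen = ev_a.explode("proteins").groupby("proteins")["sample_id"].nunique()
        assert set(seen.index) == with_peptides
        assert (seen == len(design.samples)).all()

    def test_decoys_never_cite_target_accessions(self, sim_small):
        ev_b = sim_small["ev_b"]
        decoy_accs = set().union(*ev_b.loc[ev_b["is_decoy"], "proteins"])
        target_accs = set().union(*ev_b.loc[~ev_b["is_decoy"], "proteins"])
        assert decoy_accs.isdisjoint(target_accs)
        assert all(a.startswith("DECOY_") for a in decoy_accs)

    def test_end_to_end_determinism(self):
        cfg = SimulationConfig(n_proteins=30, seed=21)
        truth = simulate_truth(cfg)
        a1, b1, _, _ = simulate_evidence(truth, cfg)
        a2, b2, _, _ = simulate_evidence(truth, cfg)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_frame_equal(b1, b2)

    def test_design_matches_study_layout(self, sim_small):
        design = sim_small["design"]
        assert design.n_control == 5 and design.n_case == 6
        assert design.control_label == "pTa" and design.case_label == "pT2+"

    def test_most_engine_a_rows_pass_default_filters(self, sim_small):
        from duoquant.psm_filter import filter_engine_a

        kept, _ = filter_engine_a(sim_small["ev_a"])
        assert 0.90 <= len(kept) / len(sim_small["ev_a"]) <= 0.99

    def test_doubling_abundance_doubles_expected_psm_rate(self):
        # one shared peptide set, two proteins at abundance a and 2a, no dropout:
        # engine-B Poisson rates must scale linearly with abundance
        cfg = SimulationConfig(n_proteins=2, de_fraction=0.0, dropout=False, seed=0)
        seq = "AAAAGGGGK" * 30
        table = pd.DataFrame(
            {
                "base_abundance": [1e5, 2e5],
                "is_de": [False, False],
                "direction": ["", ""],
                "true_fold_change": [1.0, 1.0],
                "sequence": [seq, seq],
            },
            index=pd.Index(["P1", "P2"], name="protein"),
        )
        peptides = pd.DataFrame(
            {"protein": ["P1", "P2"], "peptide": ["AAAAGGGGK", "AAAAGGGGK"], "log10_eff": [0.0, 0.0]}
        )
        peptides["theoretical_mass"] = 700.0
        counts = np.zeros(2)
        n_rep = 200
        for i in range(n_rep):
            t = SyntheticTruth(table=table, peptides=peptides, config=dataclasses.replace(cfg, seed=i))
            _, ev_b, _, _ = simulate_evidence(t)
            ev_b = ev_b.loc[~ev_b["is_decoy"]].explode("proteins")
            counts += ev_b.groupby("proteins").size().reindex(["P1", "P2"]).fillna(0).to_numpy()
        ratio = counts[1] / counts[0]
        se = ratio * np.sqrt(1 / counts[0] + 1 / counts[1])
        assert abs(ratio - 2.0) <= 3 * se


class TestRecoveryMetrics:
    @staticmethod
    def _result(tier2, directions):
        table = pd.DataFrame(
            {"protein": sorted(tier2), "direction": [directions[p] for p in sorted(tier2)]}
        )
        return ConsolidationResult(
            tier1=frozenset(), tier2=frozenset(tier2), conflicts=frozenset(),
            single_engine=frozenset(), table=table,
        )

    @staticmethod
    def _truth(de_directions, n_null=2):
        rows = {p: (True, d) for p, d in de_directions.items()}
        rows.update({f"N{i}": (False, "") for i in range(n_null)})
        table = pd.DataFrame(
            {
                "base_abundance": 1e5,
                "is_de": [v[0] for v in rows.values()],
                "direction": [v[1] for v in rows.values()],
                "true_fold_change": 1.0,
                "sequence": "AAAAAAK",
            },
            index=pd.Index(rows.keys(), name="protein"),
        )
        return SyntheticTruth(table=table, peptides=pd.DataFrame(), config=SimulationConfig())

    def test_perfect_caller(self):
        truth = self._truth({"D1": "up", "D2": "down"})
        res = self._result({"D1", "D2"}, {"D1": "up", "D2": "down"})
        assert recovery_metrics(truth, res) == {
            "sensitivity": 1.0,
            "empirical_fdr": 0.0,
            "direction_accuracy": 1.0,
        }

    def test_empty_tier2_conventions(self):
        truth = self._truth({"D1": "up"})
        res = self._result(set(), {})
        m = recovery_metrics(truth, res)
        assert m["sensitivity"] == 0.0 and m["empirical_fdr"] == 0.0

    def test_hand_built_five_protein_case(self):
        # true DE: D1 up, D2 down, D3 up; calls: D1 (up, correct), D2 (up, wrong
        # direction), N0 (false positive) -> sens 2/3, FDR 1/3, dir acc 1/2
        truth = self._truth({"D1": "up", "D2": "down", "D3": "up"}, n_null=2)
        res = self._result({"D1", "D2", "N0"}, {"D1": "up", "D2": "up", "N0": "down"})
        m = recovery_metrics(truth, res)
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["empirical_fdr"] == pytest.approx(1 / 3)
        assert m["direction_accuracy"] == pytest.approx(1 / 2)
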