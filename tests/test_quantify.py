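"""Top-3 / ppm-normalized and APEX quantification, and the tryptic digest."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duoquant.io import SampleDesign
from duoquant.quantify import (
    apex_normalize,
    apex_score,
    build_quant_matrix,
    digest_peptides,
    in_silico_digest,
    ppm_normalize,
    top3_protein_area,
)
from .conftest import make_evidence


class TestTop3:
    @pytest.mark.parametrize(
        "areas,expected",
        [([100, 50, 30, 20], 60.0), ([10, 20], 15.0), ([], 0.0), ([7], 7.0)],
    )
    def test_rollup(self, areas, expected):
        assert top3_protein_area(areas) == pytest.approx(expected)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            top3_protein_area([1.0, -2.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e6, allow_nan=False), min_size=1, max_size=12))
    def test_bounded_by_min_and_max_peptide(self, areas):
        v = top3_protein_area(areas)
        assert min(areas) - 1e-9 <= v <= max(areas) + 1e-9


class TestNormalization:
    def test_ppm_example(self):
        out = ppm_normalize({"P1": 2.0, "P2": 3.0})
        assert out["P1"] == pytest.approx(400000.0) and out["P2"] == pytest.approx(600000.0)

    def test_single_protein_gets_the_whole_scale(self):
        assert ppm_normalize({"P1": 7.0})["P1"] == pytest.approx(1e6)

    def test_all_zero_sample_warns_and_stays_zero(self, caplog):
        with caplog.at_level("WARNING"):
            out = ppm_normalize({"P1": 0.0, "P2": 0.0})
        assert (out == 0).all() and any("all-zero" in r.message for r in caplog.records)

    def test_apex_normalize(self):
        out = apex_normalize({"A": 2.0, "B": 1.0})
        assert out["A"] == pytest.approx(2 / 3) and out.sum() == pytest.approx(1.0)


def digest_oracle(seq: str, min_len: int = 6, max_len: int = 30) -> set[str]:
    """Brute-force scan digestion oracle (no regex): cut after K/R unless before P."""
    peptides, start = set(), 0
    for i, aa in enumerate(seq):
        if aa in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            peptides.add(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        peptides.add(seq[start:])
    return {p for p in peptides if min_len <= len(p) <= max_len}


class TestDigest:
    @pytest.mark.parametrize(
        "seq,expected_peps,expected_count",
        [
            ("MKRAAAAAAK", {"MK", "R", "AAAAAAK"}, 1),  # only AAAAAAK in [6, 30]
            ("KPK", {"KPK"}, 0),  # no cleavage before proline
            ("AAAAAA", {"AAAAAA"}, 1),
        ],
    )
    def test_hand_worked_examples(self, seq, expected_peps, expected_count):
        all_peps = set(digest_peptides(seq, min_len=1, max_len=1000))
        assert all_peps == expected_peps
        assert in_silico_digest(seq) == expected_count

    def test_non_alphabetic_sequence_rejected(self):
        with pytest.raises(ValueError):
            in_silico_digest("MK3R")

    def test_matches_brute_force_oracle_on_random_sequences(self):
        rng = np.random.default_rng(2024)
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            seq = "".join(rng.choice(alphabet, size=rng.integers(1, 51)))
            assert set(digest_peptides(seq)) == digest_oracle(seq), seq
            assert in_silico_digest(seq) == len(digest_oracle(seq))


class TestApexScore:
    @pytest.mark.parametrize("count,o,expected", [(4, 2, 2.0), (0, 5, 0.0), (3, 0, 3.0)])
    def test_observability_correction(self, count, o, expected):
        assert apex_score(count, o) == pytest.approx(expected)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            apex_score(-1, 3)


@pytest.fixture
def design_2() -> SampleDesign:
    return SampleDesign({"s1": "pTa", "s2": "pT2+"}, "pTa", "pT2+")


class TestBuildQuantMatrix:
    def test_singleton_normalizes_to_scale(self, design_2):
        rows = make_evidence(
            [
                {"peptide_seq": "AAAAK", "peak_area": 4.0},
                {"peptide_seq": "CCCCK", "peak_area": 6.0},
            ]
        )
        qm = build_quant_matrix(rows, design_2)
        assert qm.abundance.loc["P1", "s1"] == pytest.approx(1e6)
        assert qm.abundance.loc["P1", "s2"] == 0.0

    def test_shared_peptide_credits_every_accession(self, design_2):
        rows = make_evidence(
            [
                {"peptide_seq": "AAAAK", "proteins": ("P1", "P2"), "peak_area": 10.0},
                {"peptide_seq": "CCCCK", "proteins": ("P1",), "peak_area": 30.0},
            ]
        )
        qm = build_quant_matrix(rows, design_2)
        # P1 area = mean(10, 30) = 20, P2 area = 10 -> ppm 2/3 and 1/3
        assert qm.abundance.loc["P1", "s1"] == pytest.approx(2e6 / 3)
        assert qm.abundance.loc["P2", "s1"] == pytest.approx(1e6 / 3)

    def test_detected_only_where_observed(self, design_2):
        rows = make_evidence([{"sample_id": "s2", "peak_area": 5.0}])
        qm = build_quant_matrix(rows, design_2)
        assert not qm.detected.loc["P1", "s1"] and qm.detected.loc["P1", "s2"]

    def test_engine_b_counts_and_apex(self, design_2):
        rows = make_evidence(
            [
                {"engine": "B", "peptide_seq": "AAAAK", "peak_area": np.nan},
                {"engine": "B", "peptide_seq": "AAAAK", "peak_area": np.nan},
                {"engine": "B", "peptide_seq": "CCCCK", "proteins": ("P2",), "peak_area": np.nan},
            ]
        )
        qm = build_quant_matrix(rows, design_2, digest_index={"P1": 4, "P2": 1})
        # P1: 2 PSMs / O=4 = 0.5; P2: 1 / 1 = 1.0 -> normalized 1/3, 2/3
        assert qm.abundance.loc["P1", "s1"] == pytest.approx(1 / 3)
        assert qm.abundance.loc["P2", "s1"] == pytest.approx(2 / 3)

    def test_o_zero_protein_flagged(self, design_2):
        rows = make_evidence([{"engine": "B", "peak_area": np.nan}])
        qm = build_quant_matrix(rows, design_2, digest_index={"P1": 0})
        assert "P1" in qm.o_zero_proteins

    def test_mixed_engines_rejected(self, design_2):
        rows = make_evidence([{"engine": "A"}, {"engine": "B", "peak_area": np.nan}])
        with pytest.raises(ValueError, match="mixed engines"):
            build_quant_matrix(rows, design_2)

    def test_sample_missing_from_design_rejected(self, design_2):
        rows = make_evidence([{"sample_id": "sX"}])
        with pytest.raises(ValueError, match="missing from design"):
            build_quant_matrix(rows, design_2)

    def test_column_sums_on_simulated_data(self, sim_small):
        from duoquant.psm_filter import decoy_fdr_threshold, filter_engine_a
        from duoquant.quantify import build_digest_index

        kept_a, _ = filter_engine_a(sim_small["ev_a"])
        qa = build_quant_matrix(kept_a, sim_small["design"])
        sums = qa.abundance.sum(axis=0)
        assert np.allclose(sums[sums > 0], 1e6, rtol=1e-6)

        _, kept_b = decoy_fdr_threshold(sim_small["ev_b"])
        qb = build_quant_matrix(kept_b, sim_small["design"], build_digest_index(sim_small["fasta"]))
        sums_b = qb.abundance.sum(axis=0)
        assert np.allclose(sums_b[sums_b > 0], 1.0, atol=1e-9)

    def test_scale_invariance_of_ppm_normalization(self, sim_small):
        from duoquant.psm_filter import filter_engine_a

        kept, _ = filter_engine_a(sim_small["ev_a"])
        qm1 = build_quant_matrix(kept, sim_small["design"])
        scaled = kept.copy()
        sample = sim_small["design"].samples[0]
        mask = scaled["sample_id"] == sample
        scaled.loc[mask, "peak_area"] *= 37.5
        qm2 = build_quant_matrix(scaled, sim_small["design"])
        pd.testing.assert_frame_equal(qm1.abundance, qm2.abundance)

    def test_permutation_invariance(self, sim_small):
        from duoquant.psm_filter import filter_engine_a

        kept, _ = filter_engine_a(sim_small["ev_a"])
        qm1 = build_quant_matrix(kept, sim_small["design"])
        shuffled = kept.sample(frac=1.0, random_state=99).reset_index(drop=True)
        qm2 = build_quant_matrix(shuffled, sim_small["design"])
        pd.testing.assert_frame_equal(qm1.abundance, qm2.abundance)
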