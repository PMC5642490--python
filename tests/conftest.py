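"""Shared fixtures: hand-written evidence tables and small simulated runs."""

from __future__ import annotations

import pandas as pd
import pytest

from duoquant.io import EVIDENCE_COLUMNS, SampleDesign
from duoquant.pipeline import RunConfig, run_all
from duoquant.simulate import SimulationConfig, simulate_evidence, simulate_truth


def make_evidence(rows: list[dict]) -> pd.DataFrame:
    """Build an in-memory evidence frame from partial row dicts."""
    defaults = {
        "sample_id": "s1",
        "engine": "A",
        "peptide_seq": "PEPTIDEK",
        "proteins": ("P1",),
        "charge": 2,
        "score": 3.0,
        "observed_mass": 1000.0,
        "theoretical_mass": 1000.0,
        "peak_area": 100.0,
        "is_decoy": False,
    }
    return pd.DataFrame([{**defaults, **r} for r in rows])[EVIDENCE_COLUMNS]


@pytest.fixture
def evidence_tsv(tmp_path):
    """Write a well-formed 3-row engine-A evidence TSV and return its path."""
    lines = [
        "\t".join(EVIDENCE_COLUMNS),
        "s1\tA\tPEPTIDEK\tP1\t2\t3.0\t1000.0\t1000.0\t100.0\t0",
        "s1\tA\tAAAGGGK\tP1;P2\t3\t2.8\t800.004\t800.0\t50.0\t0",
        "s2\tA\tPEPTIDEK\tP1\t2\t2.4\t1000.001\t1000.0\t90.0\t0",
    ]
    path = tmp_path / "evidence_a.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def design_11() -> SampleDesign:
    groups = {f"pTa_{i}": "pTa" for i in range(1, 6)}
    groups.update({f"pT2+_{i}": "pT2+" for i in range(1, 7)})
    return SampleDesign(groups, "pTa", "pT2+")


@pytest.fixture(scope="session")
def sim_small():
    """A 150-protein simulated dataset (default study conditions)."""
    cfg = SimulationConfig(n_proteins=150, seed=123)
    truth = simulate_truth(cfg)
    ev_a, ev_b, design, fasta = simulate_evidence(truth, cfg)
    return {"cfg": cfg, "truth": truth, "ev_a": ev_a, "ev_b": ev_b, "design": design, "fasta": fasta}


@pytest.fixture(scope="session")
def run_small():
    """One end-to-end pipeline result on a 250-protein simulation."""
    cfg = RunConfig(simulation=SimulationConfig(n_proteins=250), seed=5)
    return cfg, run_all(cfg)
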