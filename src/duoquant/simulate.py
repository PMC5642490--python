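"""Synthetic peptide-level evidence with known ground truth.

Emulates the study design the pipeline targets — two tissue groups (pTa-like
control, n = 5, versus pT2+-like case, n = 6), on the order of 10^3 proteins
with a minority truly differential at a symmetric fold change — at the
peptide-evidence level, so that every pipeline stage (PSM filtering,
quantification, detection filtering, testing, consolidation) is exercised:

* protein base abundances are log-normal across the proteome;
* each protein gets a random amino-acid sequence (length 50-600, ~11% K/R)
  whose tryptic digest supplies its observable peptides, of which a
  geometric-like number (mean 6, truncated to [1, 30]) is actually seen;
* engine A emits one PSM per detected peptide-sample with a log-normal peak
  area (log-SD 0.4) and an XCorr drawn so ~95% of target rows pass the
  default confidence filters;
* engine B emits Poisson PSM events per peptide-sample with rate
  proportional to abundance (so a protein's rate scales with its observable
  peptide count), interleaved with lower-scoring decoy PSMs;
* dropout is logistic in log peak area, so missingness is
  abundance-dependent, and both engines see the same truth through
  independent noise.

One seeded generator drives everything; per-module substreams are derived by
stable hashing of (seed, stream name), so the seed fully determines the
output.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as _pyt_mass
from scipy.special import expit

from .consolidate import ConsolidationResult
from .io import SampleDesign, write_design, write_evidence, write_fasta
from .quantify import digest_peptides

AMINO_ACIDS = "ACDEFGHILMNPQSTVWY"  # the 18 non-K/R residues


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    n_proteins: int = 1000
    n_control: int = 5
    n_case: int = 6
    de_fraction: float = 0.10
    fold_change_de: float = 2.0  # symmetric: up x2, down /2
    peptides_mean: float = 6.0
    peptides_max: int = 30
    seq_len_range: tuple = (50, 600)
    kr_frequency: float = 0.11
    base_log10_mean: float = 5.0
    base_log10_sd: float = 0.7
    peptide_log10_sd: float = 0.3  # per-peptide ionization efficiency
    area_log_sd: float = 0.4  # natural-log SD of peak areas
    dropout: bool = True
    dropout_midpoint: float = 8.0  # ln(area) at 50% detection
    dropout_slope: float = 1.0
    ppm_error_sd: float = 2.0
    xcorr_margin_mean: float = 1.0
    xcorr_margin_sd: float = 0.6
    psm_rate_per_peptide: float = 5.0
    target_score_mean: float = 3.5
    decoy_score_mean: float = 1.8
    score_sd: float = 0.9
    decoy_fraction: float = 0.10
    engine_noise_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "n_proteins": self.n_proteins >= 1,
            "n_control": self.n_control >= 2,
            "n_case": self.n_case >= 2,
            "de_fraction": 0 <= self.de_fraction <= 1,
            "fold_change_de": self.fold_change_de >= 1,
            "peptides_mean": self.peptides_mean >= 1,
            "peptides_max": 1 <= self.peptides_max,
            "seq_len_range": 1 <= self.seq_len_range[0] <= self.seq_len_range[1],
            "kr_frequency": 0 < self.kr_frequency < 1,
            "area_log_sd": self.area_log_sd >= 0,
            "ppm_error_sd": self.ppm_error_sd >= 0,
            "psm_rate_per_peptide": self.psm_rate_per_peptide > 0,
            "decoy_fraction": 0 <= self.decoy_fraction < 1,
            "engine_noise_correlation": 0 <= self.engine_noise_correlation <= 1,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(f"invalid SimulationConfig field(s): {', '.join(bad)}")


@dataclass
class SyntheticTruth:
    """Ground truth behind one simulated dataset."""

    table: pd.DataFrame  # index protein: base_abundance, is_de, direction, true_fold_change, sequence
    peptides: pd.DataFrame  # protein, peptide, log10_eff, theoretical_mass
    config: SimulationConfig

    @property
    def de_proteins(self) -> frozenset:
        return frozenset(self.table.index[self.table["is_de"]])


def _stream(seed: int, name: str) -> np.random.Generator:
    """Independent substream keyed by a stable hash of (seed, name)."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


def _random_sequences(cfg: SimulationConfig, rng: np.random.Generator) -> list[str]:
    lo, hi = cfg.seq_len_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n_proteins)
    # K and R split the configured cleavage-site frequency ~60/40
    p_k, p_r = 0.6 * cfg.kr_frequency, 0.4 * cfg.kr_frequency
    alphabet = np.array(list(AMINO_ACIDS + "KR"))
    probs = np.concatenate([np.full(18, (1 - cfg.kr_frequency) / 18), [p_k, p_r]])
    total = int(lengths.sum())
    flat = rng.choice(alphabet, size=total, p=probs)
    seqs, pos = [], 0
    for ln in lengths:
        seqs.append("".join(flat[pos : pos + ln]))
        pos += ln
    return seqs


def simulate_truth(cfg: SimulationConfig) -> SyntheticTruth:
    """Draw the ground truth: abundances, DE labels, sequences, peptides.

    DE proteins (``round(de_fraction * n_proteins)`` of them) are split about
    half up-, half down-regulated at the configured symmetric fold change.
    """
    rng = _stream(cfg.seed, "truth")
    n = cfg.n_proteins
    proteins = [f"P{i:05d}" for i in range(1, n + 1)]
    base = 10.0 ** rng.normal(cfg.base_log10_mean, cfg.base_log10_sd, size=n)

    n_de = round(cfg.de_fraction * n)
    is_de = np.zeros(n, dtype=bool)
    is_de[rng.choice(n, size=n_de, replace=False)] = True
    direction = np.where(is_de, np.where(rng.random(n) < 0.5, "up", "down"), "")
    true_fc = np.ones(n)
    true_fc[direction == "up"] = cfg.fold_change_de
    true_fc[direction == "down"] = 1.0 / cfg.fold_change_de

    sequences = _random_sequences(cfg, rng)

    pep_rows = []
    p_geom = min(1.0, 1.0 / cfg.peptides_mean)
    for prot, seq in zip(proteins, sequences):
        observable = digest_peptides(seq)
        if not observable:
            continue
        want = min(int(rng.geometric(p_geom)), cfg.peptides_max, len(observable))
        chosen = rng.choice(len(observable), size=want, replace=False)
        for j in sorted(chosen):
            pep_rows.append((prot, observable[j]))
    peptides = pd.DataFrame(pep_rows, columns=["protein", "peptide"])
    peptides["log10_eff"] = rng.normal(0.0, cfg.peptide_log10_sd, size=len(peptides))
    uniq = {p: _pyt_mass.fast_mass(p) for p in peptides["peptide"].unique()}
    peptides["theoretical_mass"] = peptides["peptide"].map(uniq)

    table = pd.DataFrame(
        {
            "base_abundance": base,
            "is_de": is_de,
            "direction": direction,
            "true_fold_change": true_fc,
            "sequence": sequences,
        },
        index=pd.Index(proteins, name="protein"),
    )
    return SyntheticTruth(table=table, peptides=peptides, config=cfg)


def _design(cfg: SimulationConfig) -> SampleDesign:
    groups = {f"pTa_{i+1}": "pTa" for i in range(cfg.n_control)}
    groups.update({f"pT2+_{i+1}": "pT2+" for i in range(cfg.n_case)})
    return SampleDesign(groups, "pTa", "pT2+")


def _evidence_frame(data: dict) -> pd.DataFrame:
    from .io import EVIDENCE_COLUMNS

    return pd.DataFrame(data)[EVIDENCE_COLUMNS]


def simulate_evidence(truth: SyntheticTruth, cfg: SimulationConfig | None = None):
    """Generate both engines' evidence tables from the truth.

    Returns ``(evidence_A, evidence_B, design, fasta)``.  The engines share
    the truth (same abundances and fold changes) but draw independent noise
    unless ``engine_noise_correlation`` > 0, in which case engine B's
    log-abundance perturbation mixes in engine A's.
    """
    cfg = cfg or truth.config
    design = _design(cfg)
    samples = np.array(design.samples)
    n_s = len(samples)
    case_mask = np.array([design.groups[s] == design.case_label for s in samples])

    pep = truth.peptides
    n_pep = len(pep)
    prot_idx = truth.table.index.get_indexer(pep["protein"])
    ln_base = np.log(truth.table["base_abundance"].to_numpy())[prot_idx]
    ln_fc = np.log(truth.table["true_fold_change"].to_numpy())[prot_idx]
    ln_eff = pep["log10_eff"].to_numpy() * math.log(10)

    # expected ln peak area per peptide x sample
    mu = ln_base[:, None] + ln_eff[:, None] + np.where(case_mask[None, :], ln_fc[:, None], 0.0)

    xcorr_thr = np.array([1.5, 2.0, 2.5, 3.0])

    def _psm_fields(rng, n_rows, masses):
        charge = rng.choice([2, 3], size=n_rows, p=[0.7, 0.3])
        ppm_err = rng.normal(0.0, cfg.ppm_error_sd, size=n_rows)
        observed = masses * (1.0 + ppm_err * 1e-6)
        return charge, observed

    # ---------------- engine A ----------------
    rng_a = _stream(cfg.seed, "engineA")
    noise_a = rng_a.normal(0.0, 1.0, size=mu.shape)
    ln_area_a = mu + cfg.area_log_sd * noise_a
    if cfg.dropout:
        detect_a = rng_a.random(mu.shape) < expit(cfg.dropout_slope * (ln_area_a - cfg.dropout_midpoint))
    else:
        detect_a = np.ones(mu.shape, dtype=bool)
    r, c = np.nonzero(detect_a)
    masses_a = pep["theoretical_mass"].to_numpy()[r]
    charge_a, observed_a = _psm_fields(rng_a, len(r), masses_a)
    score_a = xcorr_thr[charge_a - 1] + rng_a.normal(cfg.xcorr_margin_mean, cfg.xcorr_margin_sd, size=len(r))
    ev_a = _evidence_frame(
        {
            "sample_id": samples[c],
            "engine": "A",
            "peptide_seq": pep["peptide"].to_numpy()[r],
            "proteins": [(p,) for p in pep["protein"].to_numpy()[r]],
            "charge": charge_a,
            "score": score_a,
            "observed_mass": observed_a,
            "theoretical_mass": masses_a,
            "peak_area": np.exp(ln_area_a[r, c]),
            "is_decoy": False,
        }
    )

    # ---------------- engine B ----------------
    rng_b = _stream(cfg.seed, "engineB")
    rho = cfg.engine_noise_correlation
    noise_b = rho * noise_a + math.sqrt(1 - rho**2) * rng_b.normal(0.0, 1.0, size=mu.shape)
    ln_abund_b = mu + cfg.area_log_sd * noise_b
    if cfg.dropout:
        detect_b = rng_b.random(mu.shape) < expit(cfg.dropout_slope * (ln_abund_b - cfg.dropout_midpoint))
    else:
        detect_b = np.ones(mu.shape, dtype=bool)
    mean_abund = truth.table["base_abundance"].to_numpy().mean()
    rate = cfg.psm_rate_per_peptide * np.exp(ln_abund_b) / mean_abund
    counts = rng_b.poisson(rate * detect_b)
    r_b, c_b = np.nonzero(counts)
    reps = counts[r_b, c_b]
    r_b, c_b = np.repeat(r_b, reps), np.repeat(c_b, reps)
    masses_b = pep["theoretical_mass"].to_numpy()[r_b]
    charge_b, observed_b = _psm_fields(rng_b, len(r_b), masses_b)
    score_b = rng_b.normal(cfg.target_score_mean, cfg.score_sd, size=len(r_b))
    ev_b = _evidence_frame(
        {
            "sample_id": samples[c_b],
            "engine": "B",
            "peptide_seq": pep["peptide"].to_numpy()[r_b],
            "proteins": [(p,) for p in pep["protein"].to_numpy()[r_b]],
            "charge": charge_b,
            "score": score_b,
            "observed_mass": observed_b,
            "theoretical_mass": masses_b,
            "peak_area": np.nan,
            "is_decoy": False,
        }
    )

    # decoys: shuffled-database hits with a lower score distribution
    n_decoy = int(round(cfg.decoy_fraction * len(ev_b)))
    if n_decoy:
        rng_d = _stream(cfg.seed, "decoys")
        lengths = rng_d.integers(8, 16, size=n_decoy)
        alphabet = np.array(list(AMINO_ACIDS + "KR"))
        decoy_peps = ["".join(rng_d.choice(alphabet, size=ln)) for ln in lengths]
        masses_d = np.array([_pyt_mass.fast_mass(p) for p in decoy_peps])
        charge_d, observed_d = _psm_fields(rng_d, n_decoy, masses_d)
        ev_d = _evidence_frame(
            {
                "sample_id": rng_d.choice(samples, size=n_decoy),
                "engine": "B",
                "peptide_seq": decoy_peps,
                "proteins": [(f"DECOY_{i:05d}",) for i in rng_d.integers(0, max(n_decoy, 1), size=n_decoy)],
                "charge": charge_d,
                "score": rng_d.normal(cfg.decoy_score_mean, cfg.score_sd, size=n_decoy),
                "observed_mass": observed_d,
                "theoretical_mass": masses_d,
                "peak_area": np.nan,
                "is_decoy": True,
            }
        )
        ev_b = pd.concat([ev_b, ev_d], ignore_index=True)

    fasta = dict(zip(truth.table.index, truth.table["sequence"]))
    return ev_a, ev_b, design, fasta


def recovery_metrics(truth: SyntheticTruth, result: ConsolidationResult) -> dict[str, float]:
    """Sensitivity, empirical FDR and direction accuracy of the Tier-2 call.

    * sensitivity = |tier2 ∩ true DE| / |true DE|
    * empirical_fdr = |tier2 \\ true DE| / max(|tier2|, 1)
    * direction_accuracy: fraction of recovered true positives whose
      consolidated direction matches the true direction.
    """
    true_de = truth.de_proteins
    tier2 = set(result.tier2)
    tp = tier2 & true_de
    sensitivity = len(tp) / len(true_de) if true_de else float("nan")
    fdr = len(tier2 - true_de) / max(len(tier2), 1)
    if tp:
        truth_dir = truth.table["direction"]
        called = result.table.set_index("protein")["direction"]
        correct = sum(1 for p in tp if called.get(p, "") == truth_dir[p])
        dir_acc = correct / len(tp)
    else:
        dir_acc = float("nan")
    return {"sensitivity": sensitivity, "empirical_fdr": fdr, "direction_accuracy": dir_acc}


def write_simulation(truth: SyntheticTruth, out_dir, cfg: SimulationConfig | None = None) -> dict[str, Path]:
    """Materialize one simulated dataset as the pipeline's input files."""
    cfg = cfg or truth.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ev_a, ev_b, design, fasta = simulate_evidence(truth, cfg)
    paths = {
        "evidence_A": write_evidence(ev_a, out_dir / "evidence_A.tsv"),
        "evidence_B": write_evidence(ev_b, out_dir / "evidence_B.tsv"),
        "design": write_design(design, out_dir / "design.tsv"),
        "fasta": write_fasta(fasta, out_dir / "proteins.fasta"),
    }
    truth_out = truth.table.reset_index()
    truth_out.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    paths["truth"] = out_dir / "truth.tsv"
    return paths
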