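"""Protein-level quantification from filtered peptide evidence.

Engine A (peak-area arm)
    Per sample, each peptide's abundance is rolled up over its PSMs (maximum
    area by default), the protein area is the mean of its three most intense
    peptides (fewer than three: mean of what is available; none: zero), and
    columns are ppm-normalized so each sample's protein areas sum to 10^6.

Engine B (spectral-count arm)
    Per sample, the protein's spectral count (PSM rows crediting it) is
    divided by O, its number of observable tryptic peptides — a simplified
    APEX observability correction — and columns are normalized to sum to 1.

Shared peptides are credited to every listed accession (protein grouping is
deliberately disabled; single-peptide proteins are retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import parser as _pyt_parser

from .io import SampleDesign

logger = logging.getLogger(__name__)

#: cleave C-terminal of K/R except before P (plain trypsin rule)
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass
class QuantMatrix:
    """Protein x sample abundance matrix for one engine.

    ``abundance`` is a DataFrame (rows: protein accessions, columns: sample
    ids, values >= 0).  A protein is *detected* in a sample iff its abundance
    there is strictly positive.  Engine-A columns sum to 10^6 and engine-B
    columns to 1 whenever the column has any detection.
    """

    engine_id: str
    abundance: pd.DataFrame
    o_zero_proteins: frozenset = frozenset()
    warnings: list = field(default_factory=list)

    @property
    def detected(self) -> pd.DataFrame:
        return self.abundance > 0

    @property
    def proteins(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)


def top3_protein_area(peptide_areas) -> float:
    """Mean of the three largest peptide areas (top-3 roll-up).

    Fewer than three peptides: mean of all available.  Empty input: 0
    (missing values are replaced with zero downstream).
    """
    areas = np.asarray(list(peptide_areas), dtype=float)
    if areas.size == 0:
        return 0.0
    if np.any(areas < 0):
        raise ValueError("peptide areas must be >= 0")
    if areas.size <= 3:
        return float(areas.mean())
    return float(np.sort(areas)[-3:].mean())


def ppm_normalize(raw: pd.Series | dict) -> pd.Series:
    """Scale one sample's protein areas to parts-per-million of the total.

    ``normalized = value / total * 1e6``.  An all-zero sample comes back
    unchanged with a warning.
    """
    s = pd.Series(raw, dtype=float)
    if (s < 0).any():
        raise ValueError("areas must be >= 0")
    total = s.sum()
    if total == 0:
        logger.warning("ppm_normalize: all-zero sample, returning zeros")
        return s
    return s / total * 1e6


def apex_normalize(scores: pd.Series | dict) -> pd.Series:
    """Divide one sample's APEX scores by their total (column sums to 1)."""
    s = pd.Series(scores, dtype=float)
    if (s < 0).any():
        raise ValueError("APEX scores must be >= 0")
    total = s.sum()
    if total == 0:
        logger.warning("apex_normalize: all-zero sample, returning zeros")
        return s
    return s / total


def digest_peptides(sequence: str, min_len: int = 6, max_len: int = 30, missed_cleavages: int = 0) -> list[str]:
    """Distinct fully-tryptic peptides of a sequence within a length window.

    Cleavage is C-terminal of K/R, never before P.  Returns sorted peptides
    with ``min_len <= len <= max_len``.
    """
    if not sequence or not sequence.isalpha():
        raise ValueError("sequence must be a nonempty alphabetic string")
    peps = _pyt_parser.cleave(sequence.upper(), TRYPSIN_RULE, missed_cleavages=missed_cleavages)
    return sorted(p for p in peps if min_len <= len(p) <= max_len)


def in_silico_digest(sequence: str, min_len: int = 6, max_len: int = 30, missed_cleavages: int = 0) -> int:
    """Count of observable tryptic peptides (the APEX O denominator)."""
    return len(digest_peptides(sequence, min_len, max_len, missed_cleavages))


def build_digest_index(fasta: dict[str, str], min_len: int = 6, max_len: int = 30) -> dict[str, int]:
    """Observable-peptide count per accession for a whole FASTA."""
    return {acc: in_silico_digest(seq, min_len, max_len) for acc, seq in fasta.items()}


def apex_score(spectral_count: int, o: int) -> float:
    """Spectral count corrected by observability: ``count / max(O, 1)``.

    Proteins whose digest yields no observable peptide (O = 0) fall back to a
    denominator of 1; callers flag them.
    """
    if spectral_count < 0:
        raise ValueError("spectral_count must be >= 0")
    if o < 0:
        raise ValueError("O must be >= 0")
    return spectral_count / max(o, 1)


def _explode_proteins(rows: pd.DataFrame) -> pd.DataFrame:
    """One row per (PSM, accession): shared peptides credit every accession."""
    out = rows.explode("proteins").rename(columns={"proteins": "protein"})
    return out


def build_quant_matrix(
    rows: pd.DataFrame,
    design: SampleDesign,
    digest_index: dict[str, int] | None = None,
    peptide_rollup: str = "max",
) -> QuantMatrix:
    """Turn filtered single-engine evidence into a :class:`QuantMatrix`.

    Engine A applies the top-3 / ppm-normalization path; engine B counts PSMs
    per protein, applies the APEX observability correction (``digest_index``
    or the O=1 fallback) and normalizes columns to 1.  Proteins never
    observed anywhere are absent; samples with no evidence yield an all-zero
    column and a warning.
    """
    if rows.empty:
        raise ValueError("no evidence rows to quantify")
    engines = rows["engine"].unique()
    if len(engines) != 1:
        raise ValueError(f"mixed engines in evidence: {sorted(engines)}")
    engine = engines[0]
    if rows["is_decoy"].any():
        raise ValueError("decoy rows must be filtered out before quantification")
    unknown = set(rows["sample_id"]) - set(design.samples)
    if unknown:
        raise ValueError(f"evidence samples missing from design: {sorted(unknown)}")
    if peptide_rollup not in ("max", "sum"):
        raise ValueError("peptide_rollup must be 'max' or 'sum'")

    flat = _explode_proteins(rows)
    warnings: list[str] = []
    o_zero: frozenset = frozenset()

    if engine == "A":
        # PSM -> peptide roll-up, then top-3 per (protein, sample)
        pep = (
            flat.groupby(["sample_id", "protein", "peptide_seq"], sort=False)["peak_area"]
            .agg(peptide_rollup)
            .reset_index()
        )
        prot = (
            pep.groupby(["sample_id", "protein"], sort=False)["peak_area"]
            .agg(lambda v: top3_protein_area(v.to_numpy()))
            .reset_index()
        )
        mat = prot.pivot(index="protein", columns="sample_id", values="peak_area")
    else:
        counts = flat.groupby(["sample_id", "protein"], sort=False).size().rename("count").reset_index()
        if digest_index is None:
            digest_index = {}
            warnings.append("no digest index supplied: APEX O=1 fallback for all proteins")
        o = counts["protein"].map(lambda p: digest_index.get(p, 0)).to_numpy(int)
        o_zero = frozenset(counts.loc[o == 0, "protein"])
        if o_zero and digest_index:
            warnings.append(f"{len(o_zero)} protein(s) with O=0 use denominator 1")
        counts["apex"] = counts["count"].to_numpy(float) / np.maximum(o, 1)
        mat = counts.pivot(index="protein", columns="sample_id", values="apex")

    mat = mat.reindex(columns=design.samples).fillna(0.0).sort_index()
    empty_cols = [c for c in mat.columns if mat[c].sum() == 0]
    if empty_cols:
        msg = f"sample(s) with no detections: {empty_cols}"
        warnings.append(msg)
        logger.warning(msg)
    totals = mat.sum(axis=0)
    scale = (1e6 if engine == "A" else 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = mat.div(totals.where(totals > 0, np.nan), axis=1).fillna(0.0) * scale
    return QuantMatrix(engine_id=engine, abundance=mat, o_zero_proteins=o_zero, warnings=warnings)
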