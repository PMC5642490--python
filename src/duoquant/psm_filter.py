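"""Peptide-spectrum-match confidence filtering.

Two arms, matching the two search-engine outputs:

* engine A (peak-area arm): precursor mass accuracy below 5 ppm AND a
  charge-dependent XCorr score strictly above 1.5 / 2 / 2.5 / 3 for charge
  classes 1 / 2 / 3 / >=4.  Both inequalities are strict.
* engine B (spectral-count arm): simple target-decoy false-discovery-rate
  control — the lowest score cutoff at which #decoy/#target among retained
  PSMs stays below ``fdr_max`` (default 5%).

Charge 4 is assigned to the top charge class; the FDR is estimated at the
peptide (PSM) level.  Ties at the FDR cutoff are all kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """Confidence thresholds applied before quantification.

    Parameters
    ----------
    max_ppm:
        Maximum precursor mass deviation in parts per million (strict).
    xcorr_thresholds:
        Minimum XCorr (strict) per charge class 1, 2, 3, >=4; must be
        nondecreasing.
    fdr_max:
        Target-decoy FDR bound for the spectral-count arm, in (0, 1).
    """

    max_ppm: float = 5.0
    xcorr_thresholds: tuple[float, float, float, float] = (1.5, 2.0, 2.5, 3.0)
    fdr_max: float = 0.05

    def __post_init__(self) -> None:
        if self.max_ppm <= 0:
            raise ValueError("max_ppm must be positive")
        if len(self.xcorr_thresholds) != 4:
            raise ValueError("xcorr_thresholds needs exactly 4 charge classes")
        if any(b < a for a, b in zip(self.xcorr_thresholds, self.xcorr_thresholds[1:])):
            raise ValueError("xcorr_thresholds must be nondecreasing in charge class")
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")


def mass_deviation_ppm(observed_mass, theoretical_mass):
    """Absolute precursor mass deviation in ppm.

    ``|observed - theoretical| / theoretical * 1e6``; accepts scalars or
    arrays.  Raises for nonpositive theoretical mass.
    """
    theo = np.asarray(theoretical_mass, dtype=float)
    if np.any(theo <= 0):
        raise ValueError("theoretical_mass must be > 0")
    obs = np.asarray(observed_mass, dtype=float)
    out = np.abs(obs - theo) / theo * 1e6
    return float(out) if out.ndim == 0 else out


def xcorr_threshold(charge: int, cfg: FilterConfig) -> float:
    """Threshold for a charge state; charge >= 4 uses the top class."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return cfg.xcorr_thresholds[min(charge, 4) - 1]


def passes_xcorr(charge: int, score: float, cfg: FilterConfig | None = None) -> bool:
    """True when *score* strictly exceeds the charge class threshold."""
    cfg = cfg or FilterConfig()
    return score > xcorr_threshold(charge, cfg)


def filter_engine_a(rows: pd.DataFrame, cfg: FilterConfig | None = None) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply ppm + XCorr confidence filters to engine-A evidence.

    Returns the surviving rows and a per-reason removal count
    (``decoy``, ``ppm``, ``xcorr``; a row failing both numeric filters is
    counted under each).
    """
    cfg = cfg or FilterConfig()
    if not rows.empty and (rows["engine"] != "A").any():
        raise ValueError("filter_engine_a received non-engine-A rows")
    if rows.empty:
        return rows.copy(), {"decoy": 0, "ppm": 0, "xcorr": 0}
    decoy = rows["is_decoy"].to_numpy(bool)
    ppm = mass_deviation_ppm(rows["observed_mass"].to_numpy(), rows["theoretical_mass"].to_numpy())
    # compare at 1e-9 ppm resolution so a deviation of exactly max_ppm fails
    # the strict "below" rule instead of slipping under it in binary floats
    ppm_ok = np.round(ppm, 9) < cfg.max_ppm
    thr = np.asarray(cfg.xcorr_thresholds)[np.minimum(rows["charge"].to_numpy(int), 4) - 1]
    xcorr_ok = rows["score"].to_numpy(float) > thr
    keep = ~decoy & ppm_ok & xcorr_ok
    removed = {
        "decoy": int(decoy.sum()),
        "ppm": int((~decoy & ~ppm_ok).sum()),
        "xcorr": int((~decoy & ~xcorr_ok).sum()),
    }
    logger.info("engine A filter: kept %d/%d rows, removed %s", keep.sum(), len(rows), removed)
    return rows.loc[keep].reset_index(drop=True), removed


def decoy_fdr_threshold(rows: pd.DataFrame, cfg: FilterConfig | None = None) -> tuple[float | None, pd.DataFrame]:
    """Find the lowest score cutoff with target-decoy FDR below ``fdr_max``.

    FDR at cutoff *s* is estimated as ``#decoy(score >= s) / #target(score >=
    s)``.  Returns ``(cutoff, kept target rows)``; all rows tied at the
    cutoff are kept.  If no cutoff achieves the bound, returns ``(None,
    empty)`` with a warning.
    """
    cfg = cfg or FilterConfig()
    targets = rows.loc[~rows["is_decoy"]]
    if targets.empty:
        raise ValueError("decoy_fdr_threshold requires at least one target row")
    scores = rows["score"].to_numpy(float)
    is_decoy = rows["is_decoy"].to_numpy(float)
    # per candidate cutoff (every distinct score, ascending), count rows at or
    # above it via a reversed cumulative sum — equivalent to scanning cutoffs
    # one by one but O(n log n)
    uniq, bin_idx = np.unique(scores, return_inverse=True)
    decoy_per = np.bincount(bin_idx, weights=is_decoy, minlength=len(uniq))
    total_per = np.bincount(bin_idx, minlength=len(uniq))
    decoy_ge = np.cumsum(decoy_per[::-1])[::-1]
    target_ge = np.cumsum((total_per - decoy_per)[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        passing = (target_ge > 0) & (decoy_ge / target_ge < cfg.fdr_max)
    if not passing.any():
        logger.warning("no score cutoff achieves FDR < %.3g; returning empty set", cfg.fdr_max)
        return None, targets.iloc[0:0].reset_index(drop=True)
    i = int(np.argmax(passing))  # lowest passing cutoff keeps the most rows
    s = float(uniq[i])
    kept = targets.loc[targets["score"] >= s].reset_index(drop=True)
    logger.info(
        "decoy FDR cutoff %.4g keeps %d/%d target rows (FDR estimate %.4f)",
        s, len(kept), len(targets), decoy_ge[i] / target_ge[i],
    )
    return s, kept
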