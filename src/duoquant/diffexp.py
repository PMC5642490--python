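"""Per-engine differential expression.

A protein enters testing only if detected in at least 60% of the samples of
at least one group (3/5 and 4/6 at the study's group sizes).  For retained
proteins, group means and SDs are computed with missing values as literal
zeros, the fold change is case/control (pT2+/pTa), significance is a
two-sided pooled-variance t-test at p < 0.05 (strict), and a one-sample
Kolmogorov-Smirnov normality p-value per group is reported diagnostically —
it never gates the t-test.  Benjamini-Hochberg q-values are emitted as an
extra column; the primary significance flag uses the raw p-value.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.distributions import kstwo
from statsmodels.stats.multitest import multipletests

from .io import SampleDesign
from .quantify import QuantMatrix

logger = logging.getLogger(__name__)

#: sentinel fold-change notes
CASE_ONLY = "case_only"
CONTROL_ONLY = "control_only"

DIFFEXP_COLUMNS = [
    "protein",
    "engine",
    "mean_control",
    "sd_control",
    "mean_case",
    "sd_case",
    "detect_control",
    "detect_case",
    "fold_change",
    "fc_note",
    "direction",
    "t_stat",
    "p_value",
    "q_value",
    "significant",
    "degenerate",
    "ks_p_control",
    "ks_p_case",
]


def detection_threshold(n: int, fraction: float = 0.6) -> int:
    """Smallest count k with k/n >= fraction (e.g. 3 of 5, 4 of 6 at 60%)."""
    if n < 1:
        raise ValueError("group size must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    # round before ceil so 0.6*5 == 3.0000000000000004 still maps to 3
    return int(math.ceil(round(fraction * n, 9)))


def apply_detection_filter(matrix: QuantMatrix, design: SampleDesign, fraction: float = 0.6) -> list[str]:
    """Proteins detected in >= fraction of samples of at least one group."""
    det = matrix.detected
    k_ctrl = detection_threshold(design.n_control, fraction)
    k_case = detection_threshold(design.n_case, fraction)
    n_ctrl = det[design.control_samples].sum(axis=1)
    n_case = det[design.case_samples].sum(axis=1)
    keep = (n_ctrl >= k_ctrl) | (n_case >= k_case)
    return list(det.index[keep])


def fold_change(mean_case: float, mean_control: float) -> tuple[float, str, str]:
    """Case/control abundance ratio with sentinel handling.

    Returns ``(fc, direction, note)``: control = 0 maps to ``(inf, up,
    case_only)``, case = 0 to ``(0, down, control_only)``; both zero is a
    domain error (such proteins cannot pass the detection filter).
    """
    if mean_case < 0 or mean_control < 0:
        raise ValueError("group means must be >= 0")
    if mean_case == 0 and mean_control == 0:
        raise ValueError("fold change undefined when both group means are zero")
    if mean_control == 0:
        return math.inf, "up", CASE_ONLY
    if mean_case == 0:
        return 0.0, "down", CONTROL_ONLY
    fc = mean_case / mean_control
    direction = "up" if fc > 1 else ("down" if fc < 1 else "flat")
    return fc, direction, ""


def ttest_independent(x, y, equal_var: bool = True) -> tuple[float, float, bool]:
    """Two-sided independent-sample t-test (pooled variance by default).

    Returns ``(t, p, degenerate)``.  Zero pooled variance is handled
    explicitly: equal means give ``(0, 1)``; unequal means give ``(+-inf,
    0)`` and are flagged degenerate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0, True
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0, True
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p), False


def ks_normality(values) -> float | None:
    """One-sample KS p-value against N(sample mean, sample SD); diagnostic.

    Parameters are estimated from the same sample (Lilliefors-style caveat),
    so the p-value is optimistic; it is reported, never used as a gate.
    All-identical input is degenerate and yields ``None``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError("KS normality check needs at least 3 values")
    sd = v.std(ddof=1)
    if sd == 0:
        return None
    return float(stats.kstest(v, "norm", args=(v.mean(), sd)).pvalue)


def _ks_norm_rows(M: np.ndarray) -> np.ndarray:
    """Row-wise one-sample KS p against N(row mean, row SD); NaN when SD=0.

    Matches :func:`ks_normality` (scipy's exact small-sample tail) but
    vectorized over proteins.
    """
    n = M.shape[1]
    m = M.mean(axis=1, keepdims=True)
    sd = M.std(axis=1, ddof=1, keepdims=True)
    out = np.full(M.shape[0], np.nan)
    ok = sd[:, 0] > 0
    if ok.any():
        s = np.sort(M[ok], axis=1)
        cdf = stats.norm.cdf((s - m[ok]) / sd[ok])
        i = np.arange(1, n + 1)
        d = np.maximum((i / n - cdf).max(axis=1), (cdf - (i - 1) / n).max(axis=1))
        out[ok] = np.clip(kstwo.sf(d, n), 0.0, 1.0)
    return out


def diffexp_table(
    matrix: QuantMatrix,
    design: SampleDesign,
    alpha: float = 0.05,
    fraction: float = 0.6,
    equal_var: bool = True,
    include_zeros: bool = True,
) -> pd.DataFrame:
    """Differential-expression records for proteins passing the detection rule.

    One row per retained protein; ``significant`` is the workflow's strict
    ``p < alpha`` flag on the raw p-value, with BH ``q_value`` alongside.
    With ``include_zeros=False`` missing values are excluded from means, SDs
    and tests instead of entering as zeros (off by default).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    retained = apply_detection_filter(matrix, design, fraction)
    if not retained:
        return pd.DataFrame(columns=DIFFEXP_COLUMNS)
    X = matrix.abundance.loc[retained, design.control_samples].to_numpy(float)
    Y = matrix.abundance.loc[retained, design.case_samples].to_numpy(float)

    if not include_zeros:
        return _diffexp_nonzero(matrix, retained, X, Y, alpha, equal_var)

    mx, my = X.mean(axis=1), Y.mean(axis=1)
    sx, sy = X.std(axis=1, ddof=1), Y.std(axis=1, ddof=1)
    degen = (sx == 0) & (sy == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(X, Y, axis=1, equal_var=equal_var)
    t = np.where(degen, np.where(mx == my, 0.0, np.copysign(np.inf, mx - my)), t)
    p = np.where(degen, np.where(mx == my, 1.0, 0.0), p)

    note = np.where(mx == 0, CASE_ONLY, np.where(my == 0, CONTROL_ONLY, ""))
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mx == 0, np.inf, my / np.where(mx == 0, 1.0, mx))
    direction = np.select(
        [note == CASE_ONLY, note == CONTROL_ONLY, fc > 1, fc < 1],
        ["up", "down", "up", "down"],
        default="flat",
    )

    table = pd.DataFrame(
        {
            "protein": retained,
            "engine": matrix.engine_id,
            "mean_control": mx,
            "sd_control": sx,
            "mean_case": my,
            "sd_case": sy,
            "detect_control": (X > 0).sum(axis=1),
            "detect_case": (Y > 0).sum(axis=1),
            "fold_change": fc,
            "fc_note": note,
            "direction": direction,
            "t_stat": t,
            "p_value": p,
            "significant": p < alpha,
            "degenerate": degen,
            "ks_p_control": _ks_norm_rows(X),
            "ks_p_case": _ks_norm_rows(Y),
        }
    )
    table["q_value"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    return table[DIFFEXP_COLUMNS]


def _diffexp_nonzero(matrix, retained, X, Y, alpha, equal_var) -> pd.DataFrame:
    """Zero-excluding variant (config switch): per-protein path."""
    records = []
    for i, protein in enumerate(retained):
        x, y = X[i][X[i] > 0], Y[i][Y[i] > 0]
        if x.size < 2 or y.size < 2:
            logger.warning("%s: fewer than 2 nonzero values per group; skipped", protein)
            continue
        t, p, degen = ttest_independent(x, y, equal_var=equal_var)
        fc, direction, note = fold_change(float(y.mean()), float(x.mean()))
        records.append(
            {
                "protein": protein,
                "engine": matrix.engine_id,
                "mean_control": float(x.mean()),
                "sd_control": float(x.std(ddof=1)),
                "mean_case": float(y.mean()),
                "sd_case": float(y.std(ddof=1)),
                "detect_control": int((X[i] > 0).sum()),
                "detect_case": int((Y[i] > 0).sum()),
                "fold_change": fc,
                "fc_note": note,
                "direction": direction,
                "t_stat": t,
                "p_value": p,
                "significant": p < alpha,
                "degenerate": degen,
                "ks_p_control": ks_normality(x) if x.size >= 3 else np.nan,
                "ks_p_case": ks_normality(y) if y.size >= 3 else np.nan,
            }
        )
    table = pd.DataFrame(records)
    if table.empty:
        return pd.DataFrame(columns=DIFFEXP_COLUMNS)
    table["q_value"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
    return table[DIFFEXP_COLUMNS]
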