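"""Two-tier cross-engine consolidation of differential-expression results.

Tier 1: significant in BOTH engines with agreeing direction (the
high-confidence core).  Tier 2: Tier 1 plus proteins significant in exactly
one engine whose fold change in the other engine shows the same trend at
>= 1.5-fold (ratio scale: up needs FC >= 1.5, down needs FC <= 1/1.5).
Tier 1 is always a subset of Tier 2.

Both-significant proteins with discordant directions go to a *conflict*
list, never a tier; proteins quantified by only one engine have no trend to
check in the other and are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .diffexp import CASE_ONLY, CONTROL_ONLY


@dataclass
class ConsolidationResult:
    """Tiered protein sets plus per-protein provenance."""

    tier1: frozenset
    tier2: frozenset
    conflicts: frozenset
    single_engine: frozenset
    table: pd.DataFrame  # per-protein provenance (both-engine proteins only)

    def direction_of(self, protein: str) -> str | None:
        row = self.table.loc[self.table["protein"] == protein]
        if row.empty:
            return None
        return row["direction"].iloc[0]


def trend_concordant(fc: float, fc_note: str, direction_required: str, min_fold: float = 1.5) -> bool:
    """Does the other engine's fold change show the required >= *min_fold* trend?

    ``up`` requires FC >= min_fold (or a case-only sentinel); ``down``
    requires FC <= 1/min_fold (or control-only).  ``flat`` never concords.
    """
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    if direction_required == "up":
        return fc_note == CASE_ONLY or (fc_note == "" and fc >= min_fold)
    if direction_required == "down":
        return fc_note == CONTROL_ONLY or (fc_note == "" and fc <= 1.0 / min_fold)
    return False


def consolidate_lists(table_a: pd.DataFrame, table_b: pd.DataFrame, min_fold: float = 1.5) -> ConsolidationResult:
    """Merge two engines' differential tables into Tier-1/Tier-2 sets.

    Input tables must carry ``protein``, ``significant``, ``direction``,
    ``fold_change`` and ``fc_note`` columns (as produced by
    :func:`duoquant.diffexp.diffexp_table`).  Proteins present in only one
    table are excluded from both tiers and returned in ``single_engine``.
    """
    cols = ["protein", "significant", "direction", "fold_change", "fc_note"]
    a = table_a[cols].set_index("protein") if len(table_a) else pd.DataFrame(columns=cols[1:])
    b = table_b[cols].set_index("protein") if len(table_b) else pd.DataFrame(columns=cols[1:])
    only = set(a.index).symmetric_difference(set(b.index))
    common = sorted(set(a.index) & set(b.index))

    rows = []
    tier1, tier2, conflicts = set(), set(), set()
    for p in common:
        ra, rb = a.loc[p], b.loc[p]
        sig_a, sig_b = bool(ra["significant"]), bool(rb["significant"])
        dir_a, dir_b = ra["direction"], rb["direction"]
        verdict = ""
        direction = ""
        if sig_a and sig_b:
            if dir_a == dir_b and dir_a != "flat":
                tier1.add(p)
                tier2.add(p)
                verdict = "tier1"
                direction = dir_a
            else:
                conflicts.add(p)
                verdict = "conflict"
        elif sig_a or sig_b:
            sig_dir = dir_a if sig_a else dir_b
            other = rb if sig_a else ra
            if trend_concordant(float(other["fold_change"]), other["fc_note"], sig_dir, min_fold):
                tier2.add(p)
                verdict = "tier2"
                direction = sig_dir
        rows.append(
            {
                "protein": p,
                "significant_A": sig_a,
                "significant_B": sig_b,
                "direction_A": dir_a,
                "direction_B": dir_b,
                "fold_change_A": float(ra["fold_change"]),
                "fold_change_B": float(rb["fold_change"]),
                "fc_note_A": ra["fc_note"],
                "fc_note_B": rb["fc_note"],
                "verdict": verdict,
                "direction": direction,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein",
            "significant_A",
            "significant_B",
            "direction_A",
            "direction_B",
            "fold_change_A",
            "fold_change_B",
            "fc_note_A",
            "fc_note_B",
            "verdict",
            "direction",
        ],
    )
    return ConsolidationResult(
        tier1=frozenset(tier1),
        tier2=frozenset(tier2),
        conflicts=frozenset(conflicts),
        single_engine=frozenset(only),
        table=table,
    )
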