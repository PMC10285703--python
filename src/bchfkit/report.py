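"""Heart-score incidence and distribution reporting.

Implements the binary case/control mapping (scores 1-2 control, 4-5 case,
3 excluded) and the incidence arithmetic: per-category counts and percents,
the overall score >= 4 incidence over all scored animals, and the
emergency-harvest summary. Percentages are displayed with half-even rounding
to two decimals; full precision is kept internally.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "IncidenceTable",
    "binarize_heart_score",
    "incidence_table",
    "incidence_from_counts",
    "emergency_summary",
]

SCORES = (1, 2, 3, 4, 5)


def _check_scores(scores: pd.Series) -> pd.Series:
    s = pd.Series(scores).dropna()
    if not s.isin(SCORES).all():
        bad = sorted(set(s[~s.isin(SCORES)]))
        raise ValueError(f"heart scores must lie in 1..5; found {bad}")
    return s.astype(int)


def binarize_heart_score(scores) -> pd.Series:
    """Map heart scores to 'control' (1-2), 'case' (4-5) or 'excluded' (3 or
    missing)."""
    s = pd.Series(scores)
    _check_scores(s)
    out = pd.Series("excluded", index=s.index, dtype=object)
    out[s.isin((1, 2))] = "control"
    out[s.isin((4, 5))] = "case"
    return out


@dataclasses.dataclass
class IncidenceTable:
    """Per-category counts/percents plus overall incidence figures.

    ``incidence`` uses all scored animals as denominator (the headline
    figure); ``binary_case_rate`` uses only binary-classified animals
    (score-3 animals removed from the denominator).
    """

    frame: pd.DataFrame  # index: heart score 1..5; columns: count, percent
    total: int
    incidence: float  # % with score >= 4 over all scored animals
    binary_case_rate: float  # % cases among binary-classified animals

    def __post_init__(self) -> None:
        if int(self.frame["count"].sum()) != self.total:
            raise ValueError("counts must sum to the total")
        if abs(self.frame["percent"].sum() - 100.0) > 0.05:
            raise ValueError("percents must sum to 100 up to rounding")

    def display(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["percent"] = np.round(out["percent"].to_numpy(), 2)  # half-even
        return out

    def to_markdown(self) -> str:
        disp = self.display()
        lines = ["| Heart score | N | % of total |", "| --- | --- | --- |"]
        for s, row in disp.iterrows():
            lines.append(f"| {s} | {int(row['count']):,} | {row['percent']:.2f}% |")
        lines.append(f"| overall score >=4 incidence | | {round(self.incidence, 2):.2f}% |")
        return "\n".join(lines)


def incidence_from_counts(counts) -> IncidenceTable:
    """Incidence table from per-category counts for scores 1..5."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.shape != (5,) or (counts < 0).any():
        raise ValueError("need non-negative counts for the five heart-score categories")
    total = int(counts.sum())
    if total == 0:
        raise ValueError("empty score distribution")
    percent = 100.0 * counts / total
    frame = pd.DataFrame({"count": counts, "percent": percent}, index=pd.Index(SCORES, name="heart_score"))
    incidence = 100.0 * (counts[3] + counts[4]) / total
    n_binary = counts[0] + counts[1] + counts[3] + counts[4]
    case_rate = 100.0 * (counts[3] + counts[4]) / n_binary if n_binary else float("nan")
    return IncidenceTable(frame=frame, total=total, incidence=incidence, binary_case_rate=case_rate)


def incidence_table(scores=None, group_by=None, counts=None):
    """Incidence table from raw scores (optionally per group) or from counts.

    With ``group_by`` a dict of group label -> IncidenceTable is returned in
    addition to the overall table, as ``(overall, per_group)``.
    """
    if counts is not None:
        return incidence_from_counts(counts)
    s = _check_scores(pd.Series(scores))
    if len(s) == 0:
        raise ValueError("empty score distribution")
    tab = incidence_from_counts([int((s == k).sum()) for k in SCORES])
    if group_by is None:
        return tab
    groups = pd.Series(group_by).reset_index(drop=True)
    s = s.reset_index(drop=True)
    per_group = {
        g: incidence_from_counts([int((s[groups == g] == k).sum()) for k in SCORES])
        for g in pd.unique(groups)
    }
    return tab, per_group


def emergency_summary(records: pd.DataFrame, trait_columns=None) -> pd.DataFrame:
    """Summary of emergency-harvest animals with heart score 4 or 5.

    ``records`` must carry ``heart_score`` and may carry an ``emergency``
    flag (if present, only flagged rows are used), a ``condemned`` flag and
    carcass-trait columns. Returns one row per score (4, 5) with trait
    means/SDs, counts, percent of the fragile (emergency) population, and
    condemned counts. Empty input yields an empty frame.
    """
    df = records
    if "emergency" in df.columns:
        df = df[df["emergency"].astype(bool)]
    if len(df) == 0:
        return pd.DataFrame(columns=["n", "pct_of_fragile"])
    _check_scores(df["heart_score"])
    total = len(df)
    if trait_columns is None:
        skip = {"heart_score", "emergency", "condemned", "id"}
        trait_columns = [c for c in df.columns if c not in skip and pd.api.types.is_numeric_dtype(df[c])]
    rows = {}
    for score in (4, 5):
        sub = df[df["heart_score"] == score]
        row: dict = {"n": len(sub), "pct_of_fragile": 100.0 * len(sub) / total}
        for t in trait_columns:
            row[f"{t}_mean"] = float(sub[t].mean()) if len(sub) else np.nan
            row[f"{t}_sd"] = float(sub[t].std()) if len(sub) else np.nan
        if "condemned" in df.columns:
            row["n_condemned"] = int(sub["condemned"].astype(bool).sum())
        rows[score] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "heart_score"
    out.attrs["total_emergency"] = total
    out.attrs["pct_score_4_or_5"] = 100.0 * int(df["heart_score"].isin((4, 5)).sum()) / total
    return out
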