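"""Quartile segmentation of D and the implicit/explicit comparison.

The scored cohort is cut at the empirical 25th/50th/75th percentiles of D
into four ordered groups of roughly equal size; each group is described by
its D mean, SD, range and the interpretation bands that range spans.
Explicit-scale scores (e.g. 1-4 self-report totals) are then summarized per
group and compared across the four groups with a classic one-way
fixed-effects ANOVA.  A flat explicit profile across rising implicit
quartiles is the implicit/explicit dissociation pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import classify_band

__all__ = [
    "QuartileGroups",
    "AnovaResult",
    "quartile_segment",
    "one_way_anova",
    "implicit_explicit_report",
]


@dataclass(frozen=True)
class QuartileGroups:
    """Four D-quartile groups: cut points, labels and per-group summaries."""

    cuts: tuple[float, float, float]  # Q1, Q2, Q3
    assignments: pd.Series  # participant_id -> group 1..4
    summary: pd.DataFrame  # per group: n, d mean/sd/min/max, band range


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_stats: pd.DataFrame  # per group: n, mean, sd

    def __str__(self) -> str:
        return f"F({self.df_between}, {self.df_within}) = {self.F:.3f}, p = {self.p:.3f}"


def _band_range(lo: float, hi: float) -> str:
    b_lo, b_hi = classify_band(lo).value, classify_band(hi).value
    return b_lo if b_lo == b_hi else f"{b_lo}-{b_hi}"


def quartile_segment(scores: pd.DataFrame) -> QuartileGroups:
    """Segment scored participants into four groups by D quartiles.

    Cut points are the 25/50/75 empirical percentiles (linear
    interpolation).  Assignment: d < Q1 -> group 1, [Q1, Q2) -> 2,
    [Q2, Q3) -> 3, d >= Q3 -> 4 (boundary values go up).
    """
    scored = scores.loc[~scores["excluded"] & scores["d"].notna()]
    if len(scored) < 4:
        raise ValueError(f"need at least 4 scored participants, have {len(scored)}")
    d = scored["d"].to_numpy(dtype=float)
    q1, q2, q3 = np.percentile(d, [25, 50, 75])
    group = np.where(d < q1, 1, np.where(d < q2, 2, np.where(d < q3, 3, 4)))
    for g in (1, 2, 3, 4):
        if not (group == g).any():
            raise ValueError(
                f"quartile group {g} is empty: heavy ties around the cut points "
                f"(Q1={q1:.3f}, Q2={q2:.3f}, Q3={q3:.3f})"
            )
    assignments = pd.Series(group, index=scored["participant_id"].to_numpy(), name="group")
    rows = []
    for g in (1, 2, 3, 4):
        dg = d[group == g]
        rows.append(
            {
                "group": g,
                "n": int(dg.size),
                "d_mean": float(dg.mean()),
                "d_sd": float(dg.std(ddof=1)) if dg.size > 1 else float("nan"),
                "d_min": float(dg.min()),
                "d_max": float(dg.max()),
                "band_range": _band_range(float(dg.min()), float(dg.max())),
            }
        )
    return QuartileGroups(
        cuts=(float(q1), float(q2), float(q3)),
        assignments=assignments,
        summary=pd.DataFrame(rows),
    )


def one_way_anova(groups: list[np.ndarray]) -> AnovaResult:
    """Classic fixed-effects one-way ANOVA: F = MS_between / MS_within.

    ``df_between = k - 1``, ``df_within = N - k``; p from the upper tail of
    the F distribution.  Requires >= 2 groups of >= 2 values each and some
    within-group variance.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 values each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = all_values.size - len(groups)
    if ss_within <= 0:
        raise ValueError("zero within-group variance in every group: F undefined")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within
    p = float(stats.f.sf(f, df_between, df_within))
    group_stats = pd.DataFrame(
        {
            "group": range(1, len(groups) + 1),
            "n": [g.size for g in groups],
            "mean": [g.mean() for g in groups],
            "sd": [g.std(ddof=1) for g in groups],
        }
    )
    return AnovaResult(
        F=float(f), df_between=df_between, df_within=df_within, p=p, group_stats=group_stats
    )


@dataclass(frozen=True)
class ImplicitExplicitReport:
    groups: QuartileGroups
    table: pd.DataFrame  # per group x scale: explicit mean/sd/n alongside d summary
    anovas: dict[str, AnovaResult] = field(default_factory=dict)

    def __str__(self) -> str:
        lines = ["Implicit (D quartile) vs explicit comparison", ""]
        lines.append(self.table.to_string(index=False))
        lines.append("")
        for scale, res in self.anovas.items():
            lines.append(f"{scale}: {res}")
        return "\n".join(lines)


def implicit_explicit_report(
    scores: pd.DataFrame, explicit: pd.DataFrame
) -> ImplicitExplicitReport:
    """Per-quartile explicit-score summary plus one ANOVA per scale.

    ``explicit`` has columns participant_id, scale, score; participants
    missing a scale are dropped for that scale only, so per-scale ns can
    differ.  Participants not scored on D are ignored.
    """
    required = {"participant_id", "scale", "score"}
    if not required.issubset(explicit.columns):
        raise ValueError(f"explicit table needs columns {sorted(required)}")
    groups = quartile_segment(scores)
    merged = explicit.merge(
        groups.assignments.rename("group"),
        left_on="participant_id",
        right_index=True,
        how="inner",
    )
    if merged.empty:
        raise ValueError("no participant ids overlap between D scores and explicit scores")

    rows = []
    anovas: dict[str, AnovaResult] = {}
    scales = list(dict.fromkeys(explicit["scale"]))
    for _, grow in groups.summary.iterrows():
        g = int(grow["group"])
        row = {
            "group": g,
            "n": int(grow["n"]),
            "d_mean": grow["d_mean"],
            "d_sd": grow["d_sd"],
            "d_range": f"{grow['d_min']:.3f}-{grow['d_max']:.3f}",
            "band_range": grow["band_range"],
        }
        for scale in scales:
            vals = merged.loc[
                (merged["group"] == g) & (merged["scale"] == scale), "score"
            ].to_numpy(dtype=float)
            row[f"{scale}_mean"] = float(vals.mean()) if vals.size else float("nan")
            row[f"{scale}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
            row[f"{scale}_n"] = int(vals.size)
        rows.append(row)
    for scale in scales:
        vecs = [
            merged.loc[
                (merged["group"] == g) & (merged["scale"] == scale), "score"
            ].to_numpy(dtype=float)
            for g in (1, 2, 3, 4)
        ]
        if all(v.size >= 2 for v in vecs):
            anovas[scale] = one_way_anova(vecs)
    return ImplicitExplicitReport(
        groups=groups, table=pd.DataFrame(rows), anovas=anovas
    )
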