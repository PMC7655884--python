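"""Participant-level D scoring for the seven-block IAT.

The D statistic standardizes the latency cost of the incompatible pairing
relative to the compatible pairing, separately for the two critical block
pairs (B3, B6) and (B4, B7), and averages the two quotients:

    D = 1/2 * [ (m_i1 - m_c1) / SD(B3 u B6)  +  (m_i2 - m_c2) / SD(B4 u B7) ]

where the compatible/incompatible role of (B3, B4) versus (B6, B7) follows
the task version.  Pipeline, in order: restrict to critical blocks and drop
latencies above 10,000 ms; exclude participants with more than 10% of
surviving trials under 300 ms; apply the chosen error-latency treatment;
compute block means, pooled SDs and D.  Positive D means slower responding
when "Gender violence" shares a key with "Good", i.e. implicit rejection of
intimate partner violence against women.

Two error treatments are supported.  ``builtin`` (the default) leaves
latencies untouched: the log records time to the *correct* response, so an
error's correction time is already included.  ``penalty600`` replaces each
error latency with the block's correct-trial mean plus 600 ms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .session_io import CRITICAL_BLOCKS, Session, SessionSet, TaskSpec, Trial

__all__ = [
    "Band",
    "ScoringOptions",
    "DScoreResult",
    "ScoringError",
    "trim_trials",
    "fast_response_exclusion",
    "apply_error_treatment",
    "compute_d",
    "classify_band",
    "score_cohort",
    "cohort_summary",
]

BAND_BOUNDS = (0.20, 0.50, 0.80)


class ScoringError(ValueError):
    """A session cannot be scored (empty block, degenerate latencies, ...)."""


class Band(str, enum.Enum):
    """Interpretation band for D, after the effect-size conventions.

    Half-open partition of the line: D < .20 null; .20 <= D < .50 mild;
    .50 <= D < .80 moderate; D >= .80 strong.  Negative D (implicit
    acceptance) falls in ``null``.
    """

    null = "null"
    mild = "mild"
    moderate = "moderate"
    strong = "strong"


class ScoringOptions(BaseModel):
    model_config = ConfigDict(frozen=True)

    error_treatment: Literal["builtin", "penalty600"] = "builtin"
    upper_trim_ms: float = 10_000.0
    fast_threshold_ms: float = 300.0
    fast_fraction_limit: float = 0.10
    error_penalty_ms: float = 600.0

    @model_validator(mode="after")
    def _positive(self) -> "ScoringOptions":
        if self.upper_trim_ms <= 0 or self.fast_threshold_ms <= 0:
            raise ValueError("latency thresholds must be > 0")
        if not 0 < self.fast_fraction_limit < 1:
            raise ValueError("fast_fraction_limit must lie in (0, 1)")
        return self


@dataclass(frozen=True)
class DScoreResult:
    participant_id: str
    version: int
    excluded: bool
    exclusion_reason: str | None
    fast_fraction: float
    d: float | None
    band: Band | None
    block_means: dict[int, float] | None
    pooled_sd_1: float | None  # SD over B3 u B6
    pooled_sd_2: float | None  # SD over B4 u B7
    trials_used: dict[int, int] | None


def trim_trials(session: Session, options: ScoringOptions | None = None) -> Session:
    """Restrict to critical blocks B3, B4, B6, B7 and drop over-limit latencies.

    Latencies strictly greater than ``upper_trim_ms`` are removed; a trial at
    exactly the limit is retained.  Fast (sub-300 ms) trials are kept — they
    feed participant exclusion only.
    """
    options = options or ScoringOptions()
    kept = [
        t
        for t in session.trials
        if t.block in CRITICAL_BLOCKS and t.latency_ms <= options.upper_trim_ms
    ]
    return Session(
        participant_id=session.participant_id,
        version=session.version,
        trials=kept,
        metadata=dict(session.metadata),
    )


def fast_response_exclusion(
    session: Session, options: ScoringOptions | None = None
) -> tuple[float, bool]:
    """Fraction of surviving critical trials under 300 ms, and the exclusion flag.

    The participant is excluded iff the fraction strictly exceeds
    ``fast_fraction_limit`` (default 10%).  ``session`` must already be
    trimmed (:func:`trim_trials`).
    """
    options = options or ScoringOptions()
    n = len(session.trials)
    if n == 0:
        raise ScoringError(f"participant {session.participant_id}: no scorable trials")
    fast = sum(1 for t in session.trials if t.latency_ms < options.fast_threshold_ms)
    fraction = fast / n
    return fraction, fraction > options.fast_fraction_limit


def apply_error_treatment(
    session: Session, options: ScoringOptions | None = None
) -> Session:
    """Return the session with per-trial *effective* latencies.

    ``builtin``: latencies unchanged (recorded time already runs to the
    correct response).  ``penalty600``: each error trial's latency becomes
    the mean of the correct-trial latencies in its block plus 600 ms; a block
    with errors but no correct trial is unscoreable.
    """
    options = options or ScoringOptions()
    if options.error_treatment == "builtin":
        return session

    correct_means: dict[int, float] = {}
    for block in CRITICAL_BLOCKS:
        latencies = [t.latency_ms for t in session.block_trials(block) if t.first_correct]
        if latencies:
            correct_means[block] = float(np.mean(latencies))

    new_trials: list[Trial] = []
    for t in session.trials:
        if t.first_correct:
            new_trials.append(t)
            continue
        if t.block not in correct_means:
            raise ScoringError(
                f"participant {session.participant_id}: block {t.block} has errors "
                "but no correct trials for the 600-ms penalty"
            )
        new_trials.append(
            replace(t, latency_ms=correct_means[t.block] + options.error_penalty_ms)
        )
    return Session(
        participant_id=session.participant_id,
        version=session.version,
        trials=new_trials,
        metadata=dict(session.metadata),
    )


def classify_band(d: float) -> Band:
    """Map a D score onto its interpretation band (boundaries go up)."""
    if not np.isfinite(d):
        raise ScoringError(f"non-finite d: {d}")
    lo, mid, hi = BAND_BOUNDS
    if d < lo:
        return Band.null
    if d < mid:
        return Band.mild
    if d < hi:
        return Band.moderate
    return Band.strong


def _pair_stats(
    comp: np.ndarray, incomp: np.ndarray, label: str
) -> tuple[float, float, float]:
    """(mean_comp, mean_incomp, pooled sample SD) for one block pair."""
    pooled = np.concatenate([comp, incomp])
    sd = float(np.std(pooled, ddof=1))
    if sd <= 0.0 or not np.isfinite(sd):
        raise ScoringError(f"degenerate latencies in block pair {label}")
    return float(comp.mean()), float(incomp.mean()), sd


def compute_d(
    session: Session,
    task: TaskSpec,
    options: ScoringOptions | None = None,
) -> DScoreResult:
    """Score one session through the full pipeline.

    Runs trimming, fast-response exclusion, error treatment, then the
    two-pair standardized difference.  An excluded participant gets a result
    row with the reason and no ``d``; an empty critical block or zero pooled
    SD raises :class:`ScoringError`.
    """
    options = options or ScoringOptions()
    trimmed = trim_trials(session, options)
    fast_fraction, excluded = fast_response_exclusion(trimmed, options)
    if excluded:
        return DScoreResult(
            participant_id=session.participant_id,
            version=session.version,
            excluded=True,
            exclusion_reason=(
                f"{fast_fraction:.1%} of critical trials below "
                f"{options.fast_threshold_ms:g} ms (limit {options.fast_fraction_limit:.0%})"
            ),
            fast_fraction=fast_fraction,
            d=None,
            band=None,
            block_means=None,
            pooled_sd_1=None,
            pooled_sd_2=None,
            trials_used=None,
        )

    treated = apply_error_treatment(trimmed, options)
    lat: dict[int, np.ndarray] = {}
    for block in CRITICAL_BLOCKS:
        arr = np.array([t.latency_ms for t in treated.block_trials(block)], dtype=float)
        if arr.size == 0:
            raise ScoringError(
                f"participant {session.participant_id}: block {block} empty after trimming"
            )
        lat[block] = arr

    comp_blocks = task.compatible_blocks(session.version)
    # pair 1 = (B3, B6) with the 24-trial blocks, pair 2 = (B4, B7)
    if 3 in comp_blocks:
        pairs = ((lat[3], lat[6], "B3/B6"), (lat[4], lat[7], "B4/B7"))
    else:
        pairs = ((lat[6], lat[3], "B3/B6"), (lat[7], lat[4], "B4/B7"))

    quotients: list[float] = []
    sds: list[float] = []
    for comp, incomp, label in pairs:
        m_c, m_i, sd = _pair_stats(comp, incomp, label)
        quotients.append((m_i - m_c) / sd)
        sds.append(sd)
    d = float(np.mean(quotients))

    return DScoreResult(
        participant_id=session.participant_id,
        version=session.version,
        excluded=False,
        exclusion_reason=None,
        fast_fraction=fast_fraction,
        d=d,
        band=classify_band(d),
        block_means={b: float(lat[b].mean()) for b in CRITICAL_BLOCKS},
        pooled_sd_1=sds[0],
        pooled_sd_2=sds[1],
        trials_used={b: int(lat[b].size) for b in CRITICAL_BLOCKS},
    )


def score_cohort(
    data: SessionSet, options: ScoringOptions | None = None
) -> pd.DataFrame:
    """Score every session; one row per participant.

    Columns: participant_id, version, excluded, exclusion_reason,
    fast_fraction, d, band, mean_b3/b4/b6/b7, pooled_sd_1, pooled_sd_2,
    n_b3/b4/b6/b7.  Excluded participants keep their row with ``d`` missing.
    """
    options = options or ScoringOptions()
    rows = []
    for session in data:
        r = compute_d(session, data.task, options)
        row: dict = {
            "participant_id": r.participant_id,
            "version": r.version,
            "excluded": r.excluded,
            "exclusion_reason": r.exclusion_reason,
            "fast_fraction": r.fast_fraction,
            "d": r.d,
            "band": r.band.value if r.band is not None else None,
        }
        for b in CRITICAL_BLOCKS:
            row[f"mean_b{b}"] = r.block_means[b] if r.block_means else None
        row["pooled_sd_1"] = r.pooled_sd_1
        row["pooled_sd_2"] = r.pooled_sd_2
        for b in CRITICAL_BLOCKS:
            row[f"n_b{b}"] = r.trials_used[b] if r.trials_used else None
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(scores: pd.DataFrame) -> dict:
    """Band counts and one-decimal percentages over scored participants.

    Returns ``{"n_total", "n_excluded", "n_scored", "band_counts",
    "band_percentages"}``; percentages are computed over scored (non-excluded)
    participants and rounded to one decimal.
    """
    scored = scores.loc[~scores["excluded"]]
    n_scored = len(scored)
    counts = {band.value: int((scored["band"] == band.value).sum()) for band in Band}
    if n_scored:
        percentages = {k: round(100.0 * v / n_scored, 1) for k, v in counts.items()}
    else:
        percentages = {k: float("nan") for k in counts}
    return {
        "n_total": len(scores),
        "n_excluded": int(scores["excluded"].sum()),
        "n_scored": n_scored,
        "band_counts": counts,
        "band_percentages": percentages,
    }
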