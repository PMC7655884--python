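"""Internal consistency and judge-agreement statistics.

Three families of evidence live here:

* **Split-half reliability of D.**  Within each participant and each
  critical block, trials are randomly partitioned into two near-equal
  halves; D is computed on each half; the two half-D vectors are correlated
  across participants; the correlation is stepped up with the Spearman-Brown
  prophecy formula r' = 2r/(1+r); and the whole procedure is repeated over
  many random splits (600 by default), reporting the mean corrected
  correlation.
* **Intraclass correlation**, two-way random effects, absolute agreement —
  the standard index for interchangeability of expert judges rating stimuli
  on a quantitative scale.  Values >= .75 are conventionally "excellent".
* **Aiken's V content-validity coefficient**, V = S / (n_judges * (c - 1)),
  with an exact enumeration of its null distribution (judges uniform over
  the c scale categories) for significance testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Literal

import numpy as np
import pandas as pd

from .scoring import ScoringOptions, apply_error_treatment, compute_d, trim_trials
from .session_io import CRITICAL_BLOCKS, SessionSet

__all__ = [
    "ReliabilityResult",
    "JudgeRatings",
    "IccResult",
    "read_judge_ratings",
    "split_half_reliability",
    "spearman_brown",
    "icc_absolute",
    "aiken_v",
]

EXCELLENT_ICC = 0.75


@dataclass(frozen=True)
class ReliabilityResult:
    """Distribution of Spearman-Brown-corrected split-half correlations."""

    n_splits: int
    corrected: np.ndarray  # one corrected correlation per split
    seed: int

    @property
    def mean_corrected_r(self) -> float:
        return float(np.mean(self.corrected))

    def __str__(self) -> str:
        return (
            f"split-half reliability over {self.n_splits} random splits: "
            f"mean corrected r = {self.mean_corrected_r:.3f} "
            f"(sd {np.std(self.corrected):.3f}, seed {self.seed})"
        )


@dataclass(frozen=True)
class JudgeRatings:
    """Complete items x judges integer rating matrix on a bounded scale.

    The default scale is 1..7; ``scale_min``/``scale_max`` may be relabeled
    jointly with the ratings without changing any statistic computed here.
    """

    items: list[str]
    judges: list[str]
    ratings: np.ndarray
    scale_max: int = 7
    scale_min: int = 1

    @property
    def n_categories(self) -> int:
        return self.scale_max - self.scale_min + 1

    def __post_init__(self) -> None:
        r = np.asarray(self.ratings)
        if r.shape != (len(self.items), len(self.judges)):
            raise ValueError(
                f"ratings shape {r.shape} does not match "
                f"{len(self.items)} items x {len(self.judges)} judges"
            )
        if self.n_categories < 2:
            raise ValueError("scale must have at least 2 categories")
        bad = np.argwhere((r < self.scale_min) | (r > self.scale_max) | ~np.isfinite(r))
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"rating {r[i, j]} outside [{self.scale_min}, {self.scale_max}] "
                f"for item {self.items[i]!r}, judge {self.judges[j]!r}"
            )


@dataclass(frozen=True)
class IccResult:
    value: float
    form: Literal["single", "average"]
    n_items: int
    n_judges: int

    @property
    def label(self) -> str:
        return "excellent" if self.value >= EXCELLENT_ICC else "below excellent"

    def __str__(self) -> str:
        form = "ICC(A,1)" if self.form == "single" else f"ICC(A,{self.n_judges})"
        return f"{form} = {self.value:.3f} ({self.label}, absolute agreement)"


def read_judge_ratings(
    source: str | Path | IO[str], scale_max: int = 7
) -> JudgeRatings:
    """Read a judge-rating CSV: first column item word, one column per judge."""
    df = pd.read_csv(source)
    items = df.iloc[:, 0].astype(str).tolist()
    judges = [str(c) for c in df.columns[1:]]
    return JudgeRatings(
        items=items,
        judges=judges,
        ratings=df.iloc[:, 1:].to_numpy(dtype=float),
        scale_max=scale_max,
    )


def spearman_brown(r: float) -> float:
    """Step a half-test correlation up to full length: r' = 2r / (1 + r)."""
    if r == -1:
        raise ValueError("Spearman-Brown correction undefined at r = -1")
    return 2.0 * r / (1.0 + r)


def _half_d(
    sums: dict[int, np.ndarray],
    sumsqs: dict[int, np.ndarray],
    ns: dict[int, np.ndarray],
    comp_first_pair: bool,
) -> np.ndarray:
    """D per split for one half, from per-block sufficient statistics.

    ``comp_first_pair`` is True when B3/B4 are the compatible blocks.
    Returns NaN for splits where a pooled SD degenerates.
    """
    quotients = []
    for b_early, b_late in ((3, 6), (4, 7)):
        n = ns[b_early] + ns[b_late]
        total = sums[b_early] + sums[b_late]
        ss = sumsqs[b_early] + sumsqs[b_late]
        var = (ss - total**2 / n) / (n - 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.sqrt(np.maximum(var, 0.0))
            diff = sums[b_late] / ns[b_late] - sums[b_early] / ns[b_early]
            if not comp_first_pair:
                diff = -diff
            q = np.where(sd > 0, diff / np.where(sd > 0, sd, 1.0), np.nan)
        quotients.append(q)
    return (quotients[0] + quotients[1]) / 2.0


def split_half_reliability(
    data: SessionSet,
    options: ScoringOptions | None = None,
    n_splits: int = 600,
    seed: int = 0,
    max_retries: int = 20,
) -> ReliabilityResult:
    """Random split-half reliability of D with Spearman-Brown correction.

    For every split, trials are partitioned within participant and within
    critical block into two near-equal halves (an odd trial joins a
    uniformly random half), D is computed on each half exactly as in the
    full pipeline, and the half-D vectors are correlated across
    participants.  Participants failing the fast-response exclusion are
    dropped first; error treatment is applied to the full trimmed session
    before halving.  Splits producing a degenerate pooled SD are redrawn up
    to ``max_retries`` times.

    Fully reproducible given ``seed``.
    """
    options = options or ScoringOptions()
    rng = np.random.default_rng(seed)

    # Per-participant effective latencies per critical block, exclusions applied.
    per_block: list[dict[int, np.ndarray]] = []
    comp_first: list[bool] = []
    for session in data:
        result = compute_d(session, data.task, options)
        if result.excluded:
            continue
        treated = apply_error_treatment(trim_trials(session, options), options)
        lats = {
            b: np.array([t.latency_ms for t in treated.block_trials(b)], dtype=float)
            for b in CRITICAL_BLOCKS
        }
        if any(v.size < 2 for v in lats.values()):
            raise ValueError(
                f"participant {session.participant_id}: every critical block "
                "needs at least 2 trials for split-half reliability"
            )
        per_block.append(lats)
        comp_first.append(data.task.compatible_blocks(session.version)[0] == 3)

    n_participants = len(per_block)
    if n_participants < 3:
        raise ValueError(
            f"need at least 3 scorable participants, have {n_participants}"
        )

    def draw(n: int) -> tuple[np.ndarray, np.ndarray]:
        """(n_splits x participants) half-D matrices for n fresh splits."""
        d_a = np.empty((n, n_participants))
        d_b = np.empty((n, n_participants))
        for p, lats in enumerate(per_block):
            sums_a: dict[int, np.ndarray] = {}
            sq_a: dict[int, np.ndarray] = {}
            n_a: dict[int, np.ndarray] = {}
            sums_b: dict[int, np.ndarray] = {}
            sq_b: dict[int, np.ndarray] = {}
            n_b: dict[int, np.ndarray] = {}
            for b in CRITICAL_BLOCKS:
                lat = lats[b]
                m = lat.size
                h = np.full(n, m // 2)
                if m % 2:
                    h = h + rng.integers(0, 2, size=n)
                ranks = rng.random((n, m)).argsort(axis=1).argsort(axis=1)
                mask = ranks < h[:, None]
                sums_a[b] = mask @ lat
                sq_a[b] = mask @ lat**2
                n_a[b] = h.astype(float)
                sums_b[b] = lat.sum() - sums_a[b]
                sq_b[b] = (lat**2).sum() - sq_a[b]
                n_b[b] = float(m) - n_a[b]
            d_a[:, p] = _half_d(sums_a, sq_a, n_a, comp_first[p])
            d_b[:, p] = _half_d(sums_b, sq_b, n_b, comp_first[p])
        return d_a, d_b

    def correlate(d_a: np.ndarray, d_b: np.ndarray) -> np.ndarray:
        a = d_a - d_a.mean(axis=1, keepdims=True)
        b = d_b - d_b.mean(axis=1, keepdims=True)
        denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
        num = (a * b).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
        # exact agreement with zero cross-participant spread counts as r = 1
        degenerate = denom == 0
        if degenerate.any():
            same = np.nanmax(np.abs(d_a - d_b), axis=1) < 1e-12
            r = np.where(degenerate & same, 1.0, r)
        return r

    d_a, d_b = draw(n_splits)
    r = correlate(d_a, d_b)
    bad = ~np.isfinite(r)
    retries = 0
    while bad.any() and retries < max_retries:
        d_a2, d_b2 = draw(int(bad.sum()))
        r[bad] = correlate(d_a2, d_b2)
        bad = ~np.isfinite(r)
        retries += 1
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} splits remained degenerate after {max_retries} redraws"
        )
    corrected = np.array([spearman_brown(v) for v in r])
    return ReliabilityResult(n_splits=n_splits, corrected=corrected, seed=seed)


def icc_absolute(
    ratings: JudgeRatings, form: Literal["single", "average"] = "average"
) -> IccResult:
    """Two-way random-effects, absolute-agreement intraclass correlation.

    From the items x judges mean squares (rows MSR, columns MSC, error MSE):

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
        ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

    with n items and k judges.  ``average`` (the k-rater form) is the
    default, matching a pooled expert panel.
    """
    x = np.asarray(ratings.ratings, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 items and 2 judges")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if msr <= 1e-12 * max(1.0, abs(grand)):
        raise ValueError("no between-item variance: ICC undefined")
    if form == "single":
        value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    elif form == "average":
        value = (msr - mse) / (msr + (msc - mse) / n)
    else:
        raise ValueError(f"unknown form {form!r}")
    return IccResult(value=float(value), form=form, n_items=n, n_judges=k)


def _aiken_null_tail(s_obs: np.ndarray, n_judges: int, c: int) -> np.ndarray:
    """P(S >= s_obs) when each judge rates uniformly over 1..c.

    S = sum over judges of (rating - 1); exact by convolution when the
    support is small, else a normal approximation with continuity
    correction.
    """
    support = n_judges * (c - 1)
    if support <= 2000:
        single = np.full(c, 1.0 / c)
        pmf = np.array([1.0])
        for _ in range(n_judges):
            pmf = np.convolve(pmf, single)
        cdf = np.cumsum(pmf)
        idx = np.clip(np.ceil(s_obs).astype(int), 0, support)
        tail = np.where(idx == 0, 1.0, 1.0 - cdf[np.maximum(idx - 1, 0)])
        return np.where(idx == 0, 1.0, tail)
    mean = n_judges * (c - 1) / 2.0
    var = n_judges * (c**2 - 1) / 12.0
    from scipy.stats import norm

    return norm.sf((s_obs - 0.5 - mean) / np.sqrt(var))


def aiken_v(
    ratings: JudgeRatings, critical_value: float = 0.75
) -> pd.DataFrame:
    """Per-item Aiken's V with exact null significance and elimination flags.

    V = S / (n_judges * (c - 1)) where S sums each judge's rating distance
    from the scale floor; V = 0 when every judge rates at the floor, 1 at
    the ceiling.  ``p_value`` is the upper-tail probability of the observed
    S when judges rate uniformly at random.  Items with V below
    ``critical_value`` (default .75, the conventional alpha = .01 cut) are
    flagged ``eliminate``.
    """
    x = np.asarray(ratings.ratings, dtype=float)
    n_items, n_judges = x.shape
    c = ratings.n_categories
    s = (x - ratings.scale_min).sum(axis=1)
    v = s / (n_judges * (c - 1))
    p = _aiken_null_tail(s, n_judges, c)
    return pd.DataFrame(
        {
            "item": ratings.items,
            "V": v,
            "S": s,
            "p_value": p,
            "eliminate": v < critical_value,
        }
    )
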