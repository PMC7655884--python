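"""Synthetic IAT cohorts with known ground truth.

Latencies follow an ex-Gaussian model — the sum of a Gaussian component
(mu, sigma) and an exponential tail (tau) — the standard description of
right-skewed reaction-time distributions.  Each simulated participant
carries a latent compatibility effect delta_i (ms), drawn from a normal
population distribution, that shifts every incompatible-phase latency.
On top of the clean process the simulator injects the artefacts the
scoring rules exist for: error trials (flagged, and lengthened by an
exponential recovery time, matching a forced-choice log that runs to the
correct response), fast guesses landing below the 300 ms screen, and
lapses landing above the 10,000 ms trim.

Because delta_i is known, parameter-recovery and null-calibration checks
can compare estimated D scores against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .session_io import Session, SessionSet, TaskSpec, Trial, load_task_spec

__all__ = [
    "SimParams",
    "SimTruth",
    "simulate_cohort",
    "simulate_explicit_scores",
    "simulate_judge_ratings",
]


class SimParams(BaseModel):
    """Generating parameters for one synthetic cohort.

    Defaults sketch a typical university IAT sample: ex-Gaussian base
    latencies with mean mu + tau = 850 ms and SD sqrt(sigma^2 + tau^2) =
    269 ms, a 200 ms mean compatibility effect with 80 ms between-person
    spread (placing most participants in the mild-to-strong rejection
    bands), a 5% error rate with 300 ms mean recovery, and rare fast
    guesses (1%) and lapses (0.2%).
    """

    model_config = ConfigDict(frozen=True)

    n_participants: int = 89
    version_balance: float = 0.5
    rt_mu: float = 600.0
    rt_sigma: float = 100.0
    rt_tau: float = 250.0
    effect_mean_ms: float = 200.0
    effect_sd_ms: float = 80.0
    error_rate: float = 0.05
    error_recovery_ms: float = 300.0
    fast_guess_rate: float = 0.01
    lapse_rate: float = 0.002
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "SimParams":
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.rt_sigma <= 0 or self.rt_tau <= 0:
            raise ValueError("rt_sigma and rt_tau must be > 0")
        for name in ("version_balance", "error_rate", "fast_guess_rate", "lapse_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fast_guess_rate + self.lapse_rate > 1.0:
            raise ValueError("fast_guess_rate + lapse_rate must not exceed 1")
        return self


@dataclass(frozen=True)
class SimTruth:
    """Ground truth per simulated participant, plus the generating parameters."""

    table: pd.DataFrame  # participant_id, delta_ms, version
    params: SimParams


def _block_stimuli(task: TaskSpec, block: int, n: int, rng: np.random.Generator) -> list[str]:
    """Stimulus words for one block, cycling through the relevant pool."""
    cats = task.categories
    if block in (1, 5):
        pool = list(cats["target_a"].stimuli) + list(cats["target_b"].stimuli)
    elif block == 2:
        pool = list(cats["attribute_good"].stimuli) + list(cats["attribute_bad"].stimuli)
    else:
        pool = [w for c in cats.values() for w in c.stimuli]
    order = rng.permutation(len(pool))
    return [pool[order[i % len(pool)]] for i in range(n)]


def _versions(n: int, balance: float, rng: np.random.Generator) -> np.ndarray:
    """Alternating version assignment; the fractional remainder is randomized."""
    n1 = int(np.floor(n * balance))
    frac = n * balance - n1
    if frac > 0 and rng.random() < frac:
        n1 += 1
    remaining = {1: n1, 2: n - n1}
    out = np.empty(n, dtype=int)
    want = 1
    for i in range(n):
        v = want if remaining[want] > 0 else 3 - want
        out[i] = v
        remaining[v] -= 1
        want = 3 - v
    return out


def simulate_cohort(
    params: SimParams, task: TaskSpec | None = None
) -> tuple[SessionSet, SimTruth]:
    """Generate a full cohort of 240-trial sessions plus its ground truth.

    Bit-reproducible given ``params.seed``.
    """
    task = task or load_task_spec()
    rng = np.random.default_rng(params.seed)
    versions = _versions(params.n_participants, params.version_balance, rng)
    deltas = rng.normal(params.effect_mean_ms, params.effect_sd_ms, params.n_participants)

    sessions: list[Session] = []
    width = len(str(params.n_participants))
    for i in range(params.n_participants):
        pid = f"P{i + 1:0{width}d}"
        version = int(versions[i])
        delta = float(deltas[i])
        trials: list[Trial] = []
        for spec in task.versions[version]:
            n = spec.trials
            lat = (
                rng.normal(params.rt_mu, params.rt_sigma, n)
                + rng.exponential(params.rt_tau, n)
            )
            if spec.phase == "critical_incompatible":
                lat = lat + delta
            errors = rng.random(n) < params.error_rate
            lat = lat + np.where(errors, rng.exponential(params.error_recovery_ms, n), 0.0)
            # fast guesses and lapses override the process latency
            u = rng.random(n)
            fast = u < params.fast_guess_rate
            lapse = (~fast) & (u < params.fast_guess_rate + params.lapse_rate)
            lat = np.where(fast, rng.uniform(150.0, 299.0, n), lat)
            lat = np.where(lapse, rng.uniform(10_001.0, 12_000.0, n), lat)
            lat = np.maximum(lat, 1.0)
            stimuli = _block_stimuli(task, spec.block, n, rng)
            for j in range(n):
                trials.append(
                    Trial(
                        block=spec.block,
                        trial_index=j + 1,
                        stimulus=stimuli[j],
                        latency_ms=float(lat[j]),
                        first_correct=not bool(errors[j]),
                    )
                )
        sessions.append(Session(participant_id=pid, version=version, trials=trials))

    truth = SimTruth(
        table=pd.DataFrame(
            {
                "participant_id": [s.participant_id for s in sessions],
                "delta_ms": deltas,
                "version": versions,
            }
        ),
        params=params,
    )
    return SessionSet(task=task, sessions=sessions), truth


def simulate_explicit_scores(
    truth: SimTruth,
    coupling: float = 0.0,
    scale_range: tuple[float, float] = (1.0, 4.0),
    noise_sd: float = 0.2,
    target_mean: float = 1.55,
    slope: float = 0.3,
    seed: int = 0,
    scale_name: str = "explicit",
) -> pd.DataFrame:
    """Per-participant explicit-attitude scores coupled to the latent effect.

    Scores live on ``scale_range`` (default the 1-4 self-report scale, lower
    meaning stronger rejection).  ``coupling`` in [-1, 1] sets the sign and
    strength of the dependence on the standardized latent effect delta_i;
    ``coupling = 0`` reproduces implicit/explicit dissociation — explicit
    scores hover near ``target_mean`` regardless of the implicit attitude.
    Values are clipped to the scale after adding Gaussian noise.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [-1, 1]")
    lo, hi = scale_range
    if not lo < hi:
        raise ValueError(f"invalid scale range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    delta = truth.table["delta_ms"].to_numpy(dtype=float)
    sd = delta.std()
    z = (delta - delta.mean()) / sd if sd > 0 else np.zeros_like(delta)
    scores = target_mean + slope * coupling * z + rng.normal(0.0, noise_sd, delta.size)
    scores = np.clip(scores, lo, hi)
    return pd.DataFrame(
        {
            "participant_id": truth.table["participant_id"],
            "scale": scale_name,
            "score": scores,
        }
    )


def simulate_judge_ratings(
    n_items: int = 24,
    n_judges: int = 10,
    c: int = 7,
    agreement: str = "high",
    seed: int = 0,
    item_names: list[str] | None = None,
):
    """Synthetic items x judges rating panel.

    ``high`` concentrates every judge near an item-specific target (high
    intraclass correlation); ``uniform`` draws each rating independently and
    uniformly over 1..c, the null model behind Aiken's V significance test.
    """
    from .reliability import JudgeRatings

    if n_items < 2 or n_judges < 2:
        raise ValueError("need at least 2 items and 2 judges")
    rng = np.random.default_rng(seed)
    if agreement == "high":
        targets = rng.integers(max(2, c - 3), c + 1, size=n_items)
        noise = rng.choice([-1, 0, 1], size=(n_items, n_judges), p=[0.1, 0.8, 0.1])
        ratings = np.clip(targets[:, None] + noise, 1, c)
    elif agreement == "uniform":
        ratings = rng.integers(1, c + 1, size=(n_items, n_judges))
    else:
        raise ValueError(f"unknown agreement mode {agreement!r}")
    items = item_names or [f"item{i + 1:02d}" for i in range(n_items)]
    judges = [f"judge{j + 1:02d}" for j in range(n_judges)]
    return JudgeRatings(
        items=list(items), judges=judges, ratings=ratings.astype(float), scale_max=c
    )
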