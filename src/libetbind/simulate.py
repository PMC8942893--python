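"""Synthetic Libet-clock trial logs with the structure the analysis assumes.

The generator emulates the standard temporal-binding session: per
condition, four blocks (baseline/operant × action/tone) of self-paced
trials.  Judgment errors follow an additive random-effects model

    error(participant i, block b, trial t) = μ_b + u_ib + ε_ibt,
    u_ib ~ Normal(0, τ_b),   ε_ibt ~ Normal(0, σ_trial)

with μ and the between-participant scale τ configurable per condition ×
block.  True event times follow the trial timeline of the paradigm:
self-paced key-presses, operant tones a fixed 250 ms after the action,
baseline tones uniform in a 2500–5000 ms window after clock onset, and
the clock stopping 1000–2500 ms after the judged event.  Reported clock
positions are the true phase plus the error, optionally quantized to the
nearest whole clock unit (participants report integers).

Judgment error is modeled additively on time, not on clock angle; at
realistic error magnitudes (≪ half a revolution) the two are identical
under wrap-around.

:func:`params_from_table` builds default parameters from the bundled
published block means/SDs, so simulated group summaries match the printed
tables; :func:`recovery_experiment` repeatedly pushes simulated data
through the full pipeline to measure error rates and parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import binding, inference
from .binding import BLOCKS, TRIAL_COLUMNS, TrimPolicy
from .tables import load_tables

__all__ = [
    "TrialTimeline",
    "CellParams",
    "GenerativeParams",
    "params_from_table",
    "simulate_dataset",
    "recovery_experiment",
]

#: fixed action→tone interval in operant blocks (ms)
OUTCOME_DELAY_MS = 250.0


@dataclass(frozen=True)
class TrialTimeline:
    """Event-time windows of one trial (ms since clock onset)."""

    action_window_ms: tuple[float, float] = (2560.0, 7680.0)
    outcome_delay_ms: float = OUTCOME_DELAY_MS
    baseline_tone_window_ms: tuple[float, float] = (2500.0, 5000.0)
    stop_delay_window_ms: tuple[float, float] = (1000.0, 2500.0)

    def __post_init__(self) -> None:
        for name in ("action_window_ms", "baseline_tone_window_ms", "stop_delay_window_ms"):
            lo, hi = getattr(self, name)
            if not 0 <= lo <= hi:
                raise ValueError(f"invalid window {name}={lo, hi}")
        if self.outcome_delay_ms <= 0:
            raise ValueError("operant blocks need a positive action→outcome delay")


@dataclass(frozen=True)
class CellParams:
    """Error-model parameters for one condition × block."""

    mu_ms: float
    sigma_trial_ms: float = 0.0
    tau_participant_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_trial_ms < 0 or self.tau_participant_ms < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class GenerativeParams:
    """Full specification of one simulated experiment.

    ``cells`` maps (condition, block) to :class:`CellParams`; every listed
    condition must provide all four blocks.  ``period_ms`` maps condition →
    clock period.
    """

    cells: dict[tuple[str, str], CellParams]
    period_ms: dict[str, float]
    n_participants: int = 40
    n_trials_per_block: int = 30
    n_units: int = 60
    quantize_to_units: bool = True
    seed: int = 0
    timeline: TrialTimeline = field(default_factory=TrialTimeline)

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials_per_block < 1:
            raise ValueError("need at least one participant and one trial per block")
        conds = sorted({c for c, _ in self.cells})
        for c in conds:
            have = {b for cc, b in self.cells if cc == c}
            if have != set(BLOCKS):
                raise ValueError(f"condition {c!r} missing blocks {set(BLOCKS) - have}")
            if c not in self.period_ms:
                raise ValueError(f"condition {c!r} has no period_ms")

    @property
    def conditions(self) -> list[str]:
        return sorted({c for c, _ in self.cells})


def params_from_table(
    experiment: str,
    n_participants: int | None = None,
    sigma_trial_ms: float = 70.0,
    seed: int = 0,
    quantize_to_units: bool = True,
) -> GenerativeParams:
    """Generative parameters whose group summaries match a published table.

    For each condition × block the published between-participant SD of
    block means is decomposed as SD² = τ² + σ_trial²/n_trials: τ is
    back-solved when the published SD allows it, otherwise trial noise is
    dropped for that cell (τ = SD, σ = 0).  Trial-level noise itself is not
    recoverable from group summaries; the 70 ms default is a modeling
    choice (see the methods note).
    """
    tab = load_tables()[experiment]
    n_trials = tab["n_trials_per_block"]
    cells: dict[tuple[str, str], CellParams] = {}
    period: dict[str, float] = {}
    for cond, cd in tab["conditions"].items():
        period[cond] = float(cd["period_ms"])
        for event in ("action", "tone"):
            for block in ("baseline", "operant"):
                sd = float(cd[event][block]["sd"])
                var_from_trials = sigma_trial_ms**2 / n_trials
                if sd**2 > var_from_trials:
                    tau, sig = float(np.sqrt(sd**2 - var_from_trials)), sigma_trial_ms
                else:
                    tau, sig = sd, 0.0
                cells[(cond, f"{block}_{event}")] = CellParams(
                    mu_ms=float(cd[event][block]["mean"]),
                    sigma_trial_ms=sig,
                    tau_participant_ms=tau,
                )
    return GenerativeParams(
        cells=cells,
        period_ms=period,
        n_participants=n_participants or tab["n_participants"],
        n_trials_per_block=n_trials,
        seed=seed,
        quantize_to_units=quantize_to_units,
    )


def _event_times(
    rng: np.random.Generator, block: str, n: int, timeline: TrialTimeline
) -> np.ndarray:
    lo, hi = timeline.action_window_ms
    if block == "baseline_tone":
        lo, hi = timeline.baseline_tone_window_ms
        return rng.uniform(lo, hi, n)
    action = rng.uniform(lo, hi, n)
    if block == "operant_tone":
        return action + timeline.outcome_delay_ms
    return action


def simulate_dataset(params: GenerativeParams) -> pd.DataFrame:
    """Draw one complete trial log; deterministic under ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    nt = params.n_trials_per_block
    frames = []
    pids = [f"P{i + 1:03d}" for i in range(params.n_participants)]
    for cond in params.conditions:
        per = params.period_ms[cond]
        unit = per / params.n_units
        for block in BLOCKS:
            cp = params.cells[(cond, block)]
            u = rng.normal(0.0, cp.tau_participant_ms, params.n_participants)
            eps = rng.normal(0.0, cp.sigma_trial_ms, (params.n_participants, nt))
            err = cp.mu_ms + u[:, None] + eps
            actual = np.stack(
                [_event_times(rng, block, nt, params.timeline) for _ in pids]
            )
            phase = np.mod(actual + err, per)
            units = phase / unit
            if params.quantize_to_units:
                units = np.mod(np.rint(units), params.n_units)
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": np.repeat(pids, nt),
                        "condition": cond,
                        "block": block,
                        "trial_index": np.tile(np.arange(nt), params.n_participants),
                        "actual_event_ms": actual.ravel(),
                        "reported_units": units.ravel(),
                        "period_ms": per,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def _analyze_once(trials: pd.DataFrame, trim: TrimPolicy) -> dict:
    """Trim → bind → two-way (condition × event) rm-ANOVA on one dataset."""
    annotated = binding.compute_judgment_errors(trials)
    kept, _ = binding.trim_trials(annotated, trim)
    table = binding.binding_scores(kept)
    long = table.scores.melt(
        id_vars=["participant_id", "condition"],
        value_vars=["action_binding_ms", "tone_binding_ms"],
        var_name="event",
        value_name="shift_ms",
    )
    long["event"] = long["event"].str.removesuffix("_binding_ms")
    anova = inference.rm_anova(long, "shift_ms", ["condition", "event"], "participant_id")
    return {"table": table, "anova": anova}


def recovery_experiment(
    params: GenerativeParams,
    n_replicates: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    trim: TrimPolicy = TrimPolicy(),
) -> dict:
    """Monte-Carlo calibration of the full simulate → analyze pipeline.

    Each replicate simulates a fresh dataset (seeds derived from ``seed``),
    runs trimming, binding and the condition × event rm-ANOVA, and records
    effect p-values and recovered group mean shifts.  Returns a dict with
    the per-replicate results frame, rejection rates per effect at
    ``alpha`` (type-I error under null parameters, power otherwise), and
    mean recovered shifts with Monte-Carlo SEs.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ss = np.random.SeedSequence(seed)
    rows = []
    shift_acc: list[pd.DataFrame] = []
    for i, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        res = _analyze_once(simulate_dataset(replace(params, seed=rep_seed)), trim)
        rec = {"replicate": i, "seed": rep_seed}
        for eff, r in res["anova"].iterrows():
            key = eff.replace(" × ", "_x_")
            rec[f"p_{key}"] = r["p"]
            rec[f"p_gg_{key}"] = r["p_gg"]
            rec[f"F_{key}"] = r["F"]
        rows.append(rec)
        shift_acc.append(res["table"].condition_shifts())
    results = pd.DataFrame(rows)
    rejection = {
        c.removeprefix("p_"): float((results[c] < alpha).mean())
        for c in results.columns
        if c.startswith("p_") and not c.startswith("p_gg_")
    }
    shifts = pd.concat(shift_acc, keys=range(n_replicates), names=["replicate"])
    recovered = shifts.groupby("condition").agg(["mean", "sem"])
    return {
        "results": results,
        "rejection_rates": rejection,
        "recovered_shifts": recovered,
        "n_replicates": n_replicates,
        "alpha": alpha,
    }
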