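"""Trial-level judgment errors and temporal-binding scores.

Temporal (intentional) binding is the subjective compression of the
interval between a voluntary action and its outcome: relative to
single-event baselines, actions are reported later and outcome tones
earlier.  This module turns trial logs (one row per trial) into
per-participant binding scores:

1. :func:`compute_judgment_errors` — signed circular error of every
   reported clock position against the true event time;
2. :func:`trim_trials` — within-cell outlier trimming at mean ± k·SD
   (one pass, sample SD, k = 2.5 by default);
3. :func:`binding_scores` — per participant and condition,
   action binding = mean operant-action error − mean baseline-action error
   and tone binding = mean operant-tone error − mean baseline-tone error,
   plus the group summary table (block means/SDs and shift means/SDs);
4. :func:`screen_participants` — deterministic group-level outlier
   screening (Tukey fences gated by group skewness/kurtosis).

Trial logs are plain CSV with columns
``participant_id, condition, block, trial_index, actual_event_ms,
reported_units, period_ms``; ``block`` is one of ``baseline_action,
operant_action, baseline_tone, operant_tone``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clock import ClockConfig, wrap_signed

__all__ = [
    "BLOCKS",
    "TRIAL_COLUMNS",
    "TrimPolicy",
    "TrimReport",
    "BindingTable",
    "ScreeningReport",
    "read_trials",
    "write_trials",
    "compute_judgment_errors",
    "trim_cell",
    "trim_trials",
    "binding_scores",
    "screen_participants",
    "apply_screening",
]

logger = logging.getLogger(__name__)

BLOCKS = ("baseline_action", "operant_action", "baseline_tone", "operant_tone")

TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "block",
    "trial_index",
    "actual_event_ms",
    "reported_units",
    "period_ms",
]

_CELL = ["participant_id", "condition", "block"]


class SchemaError(ValueError):
    """A trial log violates the expected CSV schema."""


def read_trials(path) -> pd.DataFrame:
    """Read a trial-log CSV, validating schema and value ranges.

    Errors name the offending column or 1-based data row.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "condition": str, "block": str})
    if df.empty:
        raise SchemaError(f"{path}: no trial rows")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad_block = df.index[~df["block"].isin(BLOCKS)]
    if len(bad_block):
        raise SchemaError(
            f"{path}: unknown block {df.loc[bad_block[0], 'block']!r} at data row "
            f"{bad_block[0] + 1}"
        )
    for col, lo in (("actual_event_ms", 0.0), ("reported_units", 0.0), ("period_ms", 1e-9)):
        bad = df.index[~(df[col] >= lo)]
        if len(bad):
            raise SchemaError(
                f"{path}: {col}={df.loc[bad[0], col]!r} out of range at data row {bad[0] + 1}"
            )
    return df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]]


def write_trials(df: pd.DataFrame, path) -> None:
    """Write a trial log in the same CSV dialect :func:`read_trials` accepts."""
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def compute_judgment_errors(
    trials: pd.DataFrame, configs: Mapping[str, ClockConfig] | None = None
) -> pd.DataFrame:
    """Annotate trials with ``error_ms``, the signed circular judgment error.

    error = reported clock phase − actual event time, wrapped to
    ``(-period/2, +period/2]``; negative means anticipatory.

    Parameters
    ----------
    trials
        Trial log (see :data:`TRIAL_COLUMNS`).
    configs
        Optional per-condition :class:`~libetbind.clock.ClockConfig`.  When
        omitted, a 60-unit clock with each trial's own ``period_ms`` is
        assumed.  When given, every condition present must have an entry and
        its period must match the trial rows.
    """
    df = trials.copy()
    if configs is not None:
        missing = sorted(set(df["condition"]) - set(configs))
        if missing:
            raise KeyError(f"no ClockConfig for condition(s) {missing}")
        n_units = df["condition"].map({c: cfg.n_units for c, cfg in configs.items()})
        period = df["condition"].map({c: cfg.period_ms for c, cfg in configs.items()})
        if not np.allclose(period.to_numpy(float), df["period_ms"].to_numpy(float)):
            raise ValueError("trial period_ms disagrees with ClockConfig.period_ms")
    else:
        n_units = pd.Series(60, index=df.index)
        period = df["period_ms"].astype(float)

    units = df["reported_units"].to_numpy(float)
    nu = n_units.to_numpy(float)
    out = (units < 0) | (units >= nu)
    if out.any():
        row = int(np.flatnonzero(out)[0])
        raise ValueError(
            f"reported_units={units[row]} outside [0, {nu[row]:g}) at data row {row + 1}"
        )
    phase = units * period.to_numpy(float) / nu
    df["error_ms"] = wrap_signed(
        phase - df["actual_event_ms"].to_numpy(float), period.to_numpy(float)
    )
    return df


@dataclass(frozen=True)
class TrimPolicy:
    """Within-cell outlier rule: keep trials with |error − mean| ≤ k·SD.

    The cell is one (participant, condition, block); mean and sample SD
    (denominator n−1) are computed once over all trials in the cell — the
    rule is not iterated.  Boundary values (|z| exactly k) are kept.
    """

    k: float = 2.5

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"k must be positive, got {self.k}")


@dataclass
class TrimReport:
    """Bookkeeping from :func:`trim_trials`."""

    n_total: int
    n_excluded: int
    #: per condition, pooled across the four binding blocks
    exclusion_by_condition: pd.Series = field(repr=False)
    #: per (participant, condition, block) cell
    exclusion_by_cell: pd.DataFrame = field(repr=False)
    warnings: list[str] = field(default_factory=list)

    @property
    def exclusion_fraction(self) -> float:
        return self.n_excluded / self.n_total if self.n_total else 0.0


def trim_cell(errors: Sequence[float], policy: TrimPolicy = TrimPolicy()) -> tuple[np.ndarray, float]:
    """Trim one cell's error list; returns (kept errors, exclusion fraction).

    Cells with fewer than two trials are kept whole (SD undefined).
    """
    e = np.asarray(errors, dtype=float)
    if e.size < 2:
        logger.warning("cell with %d trial(s): SD undefined, keeping all", e.size)
        return e, 0.0
    sd = e.std(ddof=1)
    keep = np.abs(e - e.mean()) <= policy.k * sd
    return e[keep], 1.0 - keep.mean()


def trim_trials(
    trials: pd.DataFrame, policy: TrimPolicy = TrimPolicy()
) -> tuple[pd.DataFrame, TrimReport]:
    """Apply the mean ± k·SD rule within every (participant, condition, block).

    Returns the retained trials and a :class:`TrimReport` whose
    ``exclusion_by_condition`` pools the four binding blocks, matching how
    such percentages are conventionally reported.
    """
    if "error_ms" not in trials.columns:
        raise ValueError("call compute_judgment_errors first (no error_ms column)")
    g = trials.groupby(_CELL)["error_ms"]
    mean = g.transform("mean")
    sd = g.transform("std")  # ddof=1; NaN for singleton cells
    size = g.transform("size")
    small = size < 2
    warnings = []
    if small.any():
        n_cells = trials.loc[small, _CELL].drop_duplicates().shape[0]
        warnings.append(f"{n_cells} cell(s) with < 2 trials kept untrimmed (SD undefined)")
        logger.warning(warnings[-1])
    keep = small | ((trials["error_ms"] - mean).abs() <= policy.k * sd)
    kept = trials[keep].copy()

    excl = (~keep).groupby([trials[c] for c in _CELL]).agg(["sum", "size"])
    excl.columns = ["n_excluded", "n_total"]
    excl["fraction"] = excl["n_excluded"] / excl["n_total"]
    by_cond = (~keep).groupby(trials["condition"]).mean().rename("exclusion_fraction")
    report = TrimReport(
        n_total=len(trials),
        n_excluded=int((~keep).sum()),
        exclusion_by_condition=by_cond,
        exclusion_by_cell=excl.reset_index(),
        warnings=warnings,
    )
    return kept, report


@dataclass
class BindingTable:
    """Per-participant binding scores plus the group summary.

    ``scores`` has one row per (participant, condition) with the four block
    mean raw errors, trials kept per block, per-block exclusion fractions
    (if trimming info was supplied), and the derived
    ``action_binding_ms`` / ``tone_binding_ms`` shifts.

    ``summary`` mirrors the conventional published layout: per condition and
    judged event, baseline/operant raw-error mean (SD over participants) and
    the shift mean (SD).
    """

    scores: pd.DataFrame
    summary: pd.DataFrame
    dropped: list[tuple[str, str, str]] = field(default_factory=list)

    def condition_shifts(self) -> pd.DataFrame:
        """Group mean shifts per condition, columns action/tone (ms)."""
        m = self.scores.groupby("condition")[["action_binding_ms", "tone_binding_ms"]].mean()
        return m.rename(
            columns={"action_binding_ms": "action", "tone_binding_ms": "tone"}
        )


def binding_scores(trials: pd.DataFrame, trim_report: TrimReport | None = None) -> BindingTable:
    """Reduce (trimmed) trials to per-participant binding scores.

    Action binding is the mean operant-action judgment error minus the mean
    baseline-action error; tone binding likewise for tone blocks.  A
    participant × condition pair missing any of the four blocks is dropped
    with a logged reason.  Row order of the input is irrelevant.
    """
    if "error_ms" not in trials.columns:
        raise ValueError("call compute_judgment_errors first (no error_ms column)")
    cell = trials.groupby(_CELL)["error_ms"].agg(["mean", "size"])
    wide_mean = cell["mean"].unstack("block")
    wide_n = cell["size"].unstack("block")

    dropped: list[tuple[str, str, str]] = []
    have = wide_mean.reindex(columns=BLOCKS)
    complete = have.notna().all(axis=1)
    for pid, cond in have.index[~complete]:
        missing = [b for b in BLOCKS if pd.isna(have.loc[(pid, cond), b])]
        dropped.append((str(pid), str(cond), f"missing block(s): {', '.join(missing)}"))
        logger.info("dropping participant %s condition %s: %s", pid, cond, dropped[-1][2])
    have = have[complete]
    wide_n = wide_n.reindex(index=have.index, columns=BLOCKS)

    scores = have.rename(columns={b: f"mean_{b}" for b in BLOCKS})
    scores["action_binding_ms"] = scores["mean_operant_action"] - scores["mean_baseline_action"]
    scores["tone_binding_ms"] = scores["mean_operant_tone"] - scores["mean_baseline_tone"]
    for b in BLOCKS:
        scores[f"n_kept_{b}"] = wide_n[b].astype(int)
    if trim_report is not None:
        frac = trim_report.exclusion_by_cell.set_index(_CELL)["fraction"]
        for b in BLOCKS:
            idx = pd.MultiIndex.from_tuples(
                [(p, c, b) for p, c in scores.index], names=_CELL
            )
            scores[f"excluded_frac_{b}"] = frac.reindex(idx).fillna(0.0).to_numpy()
    scores = scores.reset_index()

    summary = _group_summary(scores)
    return BindingTable(scores=scores, summary=summary, dropped=dropped)


def _group_summary(scores: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for cond, sub in scores.groupby("condition", sort=False):
        for event in ("action", "tone"):
            shift = sub[f"{event}_binding_ms"]
            for block in ("baseline", "operant"):
                raw = sub[f"mean_{block}_{event}"]
                rows.append(
                    {
                        "condition": cond,
                        "event": event,
                        "block": block,
                        "raw_mean_ms": raw.mean(),
                        "raw_sd_ms": raw.std(ddof=1),
                        "shift_mean_ms": shift.mean(),
                        "shift_sd_ms": shift.std(ddof=1),
                        "n_participants": len(sub),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class ScreeningReport:
    """Outcome of deterministic group-level participant screening.

    ``moments`` holds per-measure skewness and excess kurtosis
    (bias-corrected, as common statistics packages print them).
    ``flagged`` maps participant → list of (measure, severity) where
    severity is ``"inner"`` (beyond 1.5×IQR) or ``"outer"`` (beyond 3×IQR).
    ``excluded`` maps participant → human-readable reason;
    excluded participants are always a subset of flagged ones.
    """

    moments: pd.DataFrame
    flagged: dict[str, list[tuple[str, str]]]
    excluded: dict[str, str]

    @property
    def kept_fraction_note(self) -> str:
        return f"{len(self.excluded)} participant(s) excluded"


def screen_participants(table: BindingTable) -> ScreeningReport:
    """Flag and exclude group-level outliers on the binding measures.

    Operationalizes the conventional (subjective) boxplot-plus-moments
    screen as a deterministic rule.  For each measure (action and tone
    binding, per condition):

    * beyond the outer Tukey fence (3 × IQR past the quartiles) → excluded;
    * beyond the inner fence (1.5 × IQR) → excluded only if that measure's
      group |skewness| > 2 or |excess kurtosis| > 2 (computed before any
      exclusion); otherwise merely flagged.
    """
    wide = table.scores.pivot_table(
        index="participant_id",
        columns="condition",
        values=["action_binding_ms", "tone_binding_ms"],
    )
    if len(wide) < 5:
        raise ValueError(f"screening needs >= 5 participants, got {len(wide)}")
    wide.columns = [f"{m.removesuffix('_binding_ms')}:{c}" for m, c in wide.columns]

    moments = pd.DataFrame(
        {
            "skewness": wide.apply(lambda s: stats.skew(s.dropna(), bias=False)),
            "kurtosis": wide.apply(
                lambda s: stats.kurtosis(s.dropna(), fisher=True, bias=False)
            ),
        }
    ).rename_axis("measure")

    flagged: dict[str, list[tuple[str, str]]] = {}
    excluded: dict[str, str] = {}
    for measure in wide.columns:
        s = wide[measure].dropna()
        q1, q3 = s.quantile([0.25, 0.75])
        iqr = q3 - q1
        inner = (s < q1 - 1.5 * iqr) | (s > q3 + 1.5 * iqr)
        outer = (s < q1 - 3.0 * iqr) | (s > q3 + 3.0 * iqr)
        nonnormal = (
            abs(moments.loc[measure, "skewness"]) > 2
            or abs(moments.loc[measure, "kurtosis"]) > 2
        )
        for pid in s.index[inner]:
            sev = "outer" if outer[pid] else "inner"
            flagged.setdefault(str(pid), []).append((measure, sev))
            if sev == "outer":
                excluded[str(pid)] = f"beyond 3×IQR fence on {measure}"
            elif nonnormal and str(pid) not in excluded:
                excluded[str(pid)] = (
                    f"beyond 1.5×IQR fence on {measure} with group "
                    f"skewness/kurtosis outside ±2"
                )
    for pid, reason in excluded.items():
        logger.info("excluding participant %s: %s", pid, reason)
    return ScreeningReport(moments=moments, flagged=flagged, excluded=excluded)


def apply_screening(table: BindingTable, report: ScreeningReport) -> BindingTable:
    """Return a new :class:`BindingTable` without the excluded participants."""
    keep = ~table.scores["participant_id"].astype(str).isin(report.excluded)
    scores = table.scores[keep].reset_index(drop=True)
    return BindingTable(
        scores=scores, summary=_group_summary(scores), dropped=list(table.dropped)
    )
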