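"""Access to the bundled published group-level summary tables.

The five experiments' per-block raw judgment-error means/SDs and
operant-minus-baseline shifts ship as a YAML fixture
(``data/published_tables.yaml``).  They parameterize the synthetic trial
generator and provide the donor effects for Bayes-factor priors.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import Any

import pandas as pd
import yaml

__all__ = ["load_tables", "experiment_summary", "condition_shifts", "EXPERIMENTS"]

EXPERIMENTS = ("exp1", "exp2", "exp3", "exp4", "exp5")

BLOCKS = ("baseline_action", "operant_action", "baseline_tone", "operant_tone")


@lru_cache(maxsize=1)
def load_tables() -> dict[str, Any]:
    """Return the raw nested dict of all bundled experiment tables."""
    ref = resources.files("libetbind").joinpath("data/published_tables.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def experiment_summary(experiment: str) -> pd.DataFrame:
    """Published block-level summary of one experiment, long format.

    Columns: condition, event (action/tone), block (baseline/operant),
    mean, sd, period_ms, plus shift_mean/shift_sd repeated per event.
    """
    tab = _get(experiment)
    rows = []
    for cond, cd in tab["conditions"].items():
        for event in ("action", "tone"):
            for block in ("baseline", "operant"):
                rows.append(
                    {
                        "condition": cond,
                        "event": event,
                        "block": block,
                        "mean": cd[event][block]["mean"],
                        "sd": cd[event][block]["sd"],
                        "shift_mean": cd[event]["shift"]["mean"],
                        "shift_sd": cd[event]["shift"]["sd"],
                        "period_ms": cd["period_ms"],
                    }
                )
    return pd.DataFrame(rows)


def condition_shifts(experiment: str) -> pd.DataFrame:
    """Published mean shifts, one row per condition, columns action/tone (ms)."""
    tab = _get(experiment)
    data = {
        cond: {
            "action": cd["action"]["shift"]["mean"],
            "tone": cd["tone"]["shift"]["mean"],
        }
        for cond, cd in tab["conditions"].items()
    }
    return pd.DataFrame(data).T.rename_axis("condition")


def _get(experiment: str) -> dict[str, Any]:
    tables = load_tables()
    if experiment not in tables:
        raise KeyError(
            f"unknown experiment {experiment!r}; available: {sorted(tables)}"
        )
    return tables[experiment]
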