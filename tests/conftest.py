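import numpy as np
import pandas as pd
import pytest

from libetbind.simulate import CellParams, GenerativeParams


def null_params(
    n_participants: int = 40,
    sigma_trial: float = 70.0,
    tau: float = 60.0,
    seed: int = 0,
) -> GenerativeParams:
    """Three-speed design with identical block means across conditions."""
    mus = {
        "baseline_action": -20.0,
        "operant_action": 5.0,
        "baseline_tone": -30.0,
        "operant_tone": -100.0,
    }
    cells = {
        (c, b): CellParams(mu_ms=mus[b], sigma_trial_ms=sigma_trial, tau_participant_ms=tau)
        for c in ("1280", "2560", "5120")
        for b in mus
    }
    return GenerativeParams(
        cells=cells,
        period_ms={"1280": 1280.0, "2560": 2560.0, "5120": 5120.0},
        n_participants=n_participants,
        seed=seed,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture()
def toy_within():
    """8 participants × 3 speeds × 2 events of Gaussian cell means."""
    r = np.random.default_rng(11)
    rows = []
    for i in range(8):
        base = r.normal(0, 20)
        for j, cond in enumerate(["1280", "2560", "5120"]):
            for k, event in enumerate(["action", "tone"]):
                rows.append(
                    {
                        "participant_id": f"P{i}",
                        "condition": cond,
                        "event": event,
                        "shift_ms": base + 10 * j - 40 * k + 5 * j * k + r.normal(0, 15),
                    }
                )
    return pd.DataFrame(rows)
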