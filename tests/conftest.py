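import numpy as np
import pandas as pd
import pytest

from cueloc import SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """Eight simulated participants at default parameters; shared read-only."""
    cfg = SimulationConfig(n_participants=8, seed=7)
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def default_experiment():
    """Full-size (23-participant) simulated study; shared read-only."""
    cfg = SimulationConfig(seed=42)
    return generate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_trials(rows):
    """Build a minimal trials table from (pid, oid, studied, immediate,
    delayed1, delayed2, rounds, status, rating) tuples."""
    recs = []
    for pid, oid, stu, imm, d1, d2, rounds, status, rating in rows:
        recs.append({
            "participant_id": pid, "object_id": oid,
            "studied_x": stu[0], "studied_y": stu[1],
            "immediate_x": imm[0], "immediate_y": imm[1],
            "delayed1_x": d1[0], "delayed1_y": d1[1],
            "delayed2_x": d2[0], "delayed2_y": d2[1],
            "n_training_rounds": rounds, "cue_status": status,
            "rating": rating})
    return pd.DataFrame(recs)
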