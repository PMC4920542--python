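import hypothesis
import numpy as np
import pytest

import rlcontext.models as m
import rlcontext.simulate as sim
import rlcontext.task as tk

hypothesis.settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=25
)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def contexts():
    return tk.make_default_contexts()


@pytest.fixture(scope="session")
def m3_params():
    return m.Parameters(beta=5.0, alpha1=0.3, alpha2=0.3, alpha3=0.3)


@pytest.fixture(scope="session")
def m1_params():
    return m.Parameters(beta=5.0, alpha1=0.3)


@pytest.fixture(scope="session")
def m3_session(m3_params):
    """One 80-trial session simulated from the full model."""
    history, final = sim.simulate_agent(m.Model.M3, m3_params, seed=20260901)
    return history, final


@pytest.fixture(scope="session")
def m1_cohort(m1_params):
    """Twelve sessions simulated from basic Q-learning."""
    rng = np.random.default_rng(11)
    return [
        sim.simulate_agent(
            m.Model.M1, m1_params, seed=int(rng.integers(2**31)), subject_id=f"s{i:02d}"
        )[0]
        for i in range(12)
    ]


def make_history(contexts, context_idx, chosen, r_c, r_u, subject_id="manual"):
    """Build a SessionHistory from plain lists; r_u entries of None become NaN."""
    context_idx = np.asarray(context_idx, dtype=np.int64)
    complete = np.array(
        [contexts[s].feedback is tk.Feedback.COMPLETE for s in context_idx]
    )
    r_u = np.array([np.nan if v is None else float(v) for v in r_u])
    return tk.SessionHistory(
        subject_id=subject_id,
        contexts=contexts,
        context_idx=context_idx,
        chosen=np.asarray(chosen, dtype=np.int64),
        r_c=np.asarray(r_c, dtype=np.float64),
        r_u=r_u,
        complete=complete,
    )
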