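"""Hot loops for likelihood evaluation and history replay.

These replay a session with scalar arithmetic and are jit-compiled with
numba; they must stay numerically equivalent to the step-by-step API in
:mod:`rlcontext.models` (asserted in the test suite). If numba is
unavailable the plain-Python definitions are used unchanged.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=True)
def _softplus(x: float) -> float:
    # log(1 + exp(x)), safe for large |x|
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True)
def nll_kernel(
    beta: float,
    a1: float,
    a2: float,
    a3: float,
    ctx: np.ndarray,
    chosen: np.ndarray,
    r_c: np.ndarray,
    r_u: np.ndarray,
    complete: np.ndarray,
    n_ctx: int,
) -> float:
    """Negative log-likelihood of a session under the full update rule.

    M1/M2/M4 are obtained by passing their pinned learning rates as 0.
    """
    q = np.zeros((n_ctx, 2))
    v = np.zeros(n_ctx)
    nll = 0.0
    for t in range(ctx.shape[0]):
        s = ctx[t]
        c = chosen[t]
        u = 1 - c
        nll += _softplus(beta * (q[s, u] - q[s, c]))
        dc = r_c[t] - v[s] - q[s, c]
        if complete[t]:
            du = r_u[t] - v[s] - q[s, u]
            r_tot = (r_c[t] + r_u[t]) / 2.0
        else:
            du = 0.0
            r_tot = (r_c[t] + q[s, u]) / 2.0
        dv = r_tot - v[s]
        q[s, c] += a1 * dc
        q[s, u] += a2 * du
        v[s] += a3 * dv
    return nll


@njit(cache=True)
def replay_pcorrect_kernel(
    beta: float,
    a1: float,
    a2: float,
    a3: float,
    ctx: np.ndarray,
    chosen: np.ndarray,
    r_c: np.ndarray,
    r_u: np.ndarray,
    complete: np.ndarray,
    n_ctx: int,
) -> np.ndarray:
    """Per-trial probability of the correct option (option 0), evaluated
    before each trial's outcome is observed, replaying the given history."""
    q = np.zeros((n_ctx, 2))
    v = np.zeros(n_ctx)
    out = np.empty(ctx.shape[0])
    for t in range(ctx.shape[0]):
        s = ctx[t]
        c = chosen[t]
        u = 1 - c
        out[t] = np.exp(-_softplus(beta * (q[s, 1] - q[s, 0])))
        dc = r_c[t] - v[s] - q[s, c]
        if complete[t]:
            du = r_u[t] - v[s] - q[s, u]
            r_tot = (r_c[t] + r_u[t]) / 2.0
        else:
            du = 0.0
            r_tot = (r_c[t] + q[s, u]) / 2.0
        dv = r_tot - v[s]
        q[s, c] += a1 * dc
        q[s, u] += a2 * du
        v[s] += a3 * dv
    return out
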