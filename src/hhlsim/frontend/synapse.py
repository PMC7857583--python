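"""Three-pool ribbon-synapse vesicle model and release-train sampling.

The synapse holds a quantal immediate store q (capacity M), a
continuous cleft content c and a continuous reprocessing store w.  Per
unit time, each of the q docked vesicles is released into the cleft
with hazard k(t) (the per-vesicle rate from the IHC calcium chain);
cleft transmitter is lost at rate l or recovered into w at rate r;
recovered vesicles rejoin the immediate store at rate x; and new
vesicles are manufactured into free docking sites at rate y (M - q).

Released-vesicle counts are the model's output: each release event
drives one postsynaptic conductance pulse on the fiber.  Two sampling
modes exist:

- ``pools``: the full stochastic scheme above.  Quantal transitions use
  exact exponential hazards (probability 1 - exp(-rate dt) per vesicle
  per step), so no step-size restriction arises even during the onset
  burst when k is large.
- ``poisson``: an inhomogeneous Poisson process driven by the *expected*
  release rate q_bar(t) k(t) from the deterministic pool equations; the
  simpler model that reproduces the same population behavior.

Reproducibility: each (master seed, trial, synapse) triple maps to an
independent numpy Philox stream, so adding or removing fibers never
perturbs other fibers' draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

RELEASE_MODELS = ("pools", "poisson")


@dataclass(frozen=True)
class PoolParams:
    """Vesicle-pool constants (rates in 1/s)."""

    M: int = 10
    x: float = 66.31
    y: float = 10.0
    l: float = 2580.0
    r: float = 6580.0

    def __post_init__(self):
        if self.M < 1:
            raise ValueError("M must be a positive integer")
        for name in ("x", "y", "l", "r"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name} must be >= 0")

    def steady_state(self, k_rest: float):
        """(q, c, w) equilibrium under a constant per-vesicle rate k_rest."""
        denom = self.y + k_rest * self.l / (self.l + self.r) \
            if (self.l + self.r) > 0 else self.y + k_rest
        q = self.M * self.y / denom if denom > 0 else float(self.M)
        rate = q * k_rest
        c = rate / (self.l + self.r) if (self.l + self.r) > 0 else 0.0
        w = self.r * c / self.x if self.x > 0 else 0.0
        return q, c, w


def expected_release_rate(
    k_per_s: np.ndarray,
    dt_ms: float,
    pools: PoolParams,
    initial: tuple[float, float, float] | None = None,
    return_pools: bool = False,
):
    """Deterministic expected release rate q(t) k(t) in releases/s.

    Integrates the pool equations with continuous q, starting from the
    equilibrium under k(0) (or from ``initial`` = (q, c, w)).  With
    ``return_pools`` the (q, c, w) trajectories are returned as well.
    """
    k = np.asarray(k_per_s, dtype=float)
    out = np.empty_like(k)
    traj = np.empty((3, k.size) if return_pools else (3, 0))
    if initial is None:
        q0, c0, w0 = pools.steady_state(float(k[0]))
    else:
        q0, c0, w0 = initial
    _expected_kernel(
        k, dt_ms * 1e-3, float(pools.M), pools.x, pools.y, pools.l, pools.r,
        q0, c0, w0, out, traj,
    )
    if return_pools:
        return out, traj[0], traj[1], traj[2]
    return out


@njit(cache=True)
def _expected_kernel(k, dt_s, M, x, y, l, r, q, c, w, out, traj):
    record = traj.shape[1] > 0
    for i in range(k.size):
        rel = q * k[i]
        dq = x * w + y * (M - q) - rel
        dc = rel - (l + r) * c
        dw = r * c - x * w
        q = min(max(q + dt_s * dq, 0.0), M)
        c = max(c + dt_s * dc, 0.0)
        w = max(w + dt_s * dw, 0.0)
        out[i] = rel
        if record:
            traj[0, i] = q
            traj[1, i] = c
            traj[2, i] = w
    return 0


@njit(cache=True)
def _nb_seed(seed):
    # numba kernels use their own internal RNG state; it must be seeded
    # from inside compiled code
    np.random.seed(seed)
    return 0


@njit(cache=True)
def _pool_sample_kernel(k, dt_s, M, x, y, l, r, q0, c0, w0,
                        rel_steps, rel_q):
    """Stochastic pool simulation; returns number of release events.

    rel_steps/rel_q are output buffers (step index, uniform jitter slot).
    """
    q = q0
    c = c0
    w = w0
    n_out = 0
    for i in range(k.size):
        p_rel = 1.0 - np.exp(-k[i] * dt_s)
        n_rel = np.random.binomial(q, p_rel) if q > 0 else 0
        # continuous-store transfers, quantal on arrival into q
        n_ref = np.random.poisson(x * w * dt_s) if w > 0 else 0
        if n_ref > w:
            n_ref = int(w)
        free = M - q + n_rel - n_ref
        n_new = np.random.poisson(y * free * dt_s) if free > 0 else 0
        if n_new > free:
            n_new = free
        q = q - n_rel + n_ref + n_new
        c = max(c + n_rel - (l + r) * c * dt_s, 0.0)
        w = max(w + r * c * dt_s - n_ref, 0.0)
        for _ in range(n_rel):
            if n_out < rel_steps.size:
                rel_steps[n_out] = i
                rel_q[n_out] = np.random.random()
                n_out += 1
    return n_out


@njit(cache=True)
def _poisson_sample_kernel(rate, dt_s, rel_steps, rel_q):
    n_out = 0
    for i in range(rate.size):
        p = 1.0 - np.exp(-rate[i] * dt_s)
        if np.random.random() < p:
            if n_out < rel_steps.size:
                rel_steps[n_out] = i
                rel_q[n_out] = np.random.random()
                n_out += 1
    return n_out


def _seed_for(master_seed: int, trial: int, synapse_id: int) -> int:
    """Derive a 32-bit stream seed from (master seed, trial, synapse)."""
    ss = np.random.SeedSequence([master_seed, trial, synapse_id])
    return int(ss.generate_state(1, np.uint32)[0])


def sample_release_train(
    k_per_s: np.ndarray,
    dt_ms: float,
    pools: PoolParams | None = None,
    model: str = "pools",
    master_seed: int = 0,
    trial: int = 0,
    synapse_id: int = 0,
    max_events: int = 4096,
) -> np.ndarray:
    """Sample one release train (sorted times in ms) for one synapse.

    ``k_per_s`` is the per-vesicle rate for ``model="pools"`` and the
    total expected release rate for ``model="poisson"``.  Event times
    are jittered uniformly within their 5-us step so trains are
    strictly increasing.
    """
    if model not in RELEASE_MODELS:
        raise ValueError(f"unknown release model {model!r}")
    k = np.ascontiguousarray(k_per_s, dtype=np.float64)
    dt_s = dt_ms * 1e-3
    rel_steps = np.empty(max_events, dtype=np.int64)
    rel_q = np.empty(max_events, dtype=np.float64)
    seed = _seed_for(master_seed, trial, synapse_id)
    _nb_seed(seed)
    if model == "pools":
        if pools is None:
            pools = PoolParams()
        q0, c0, w0 = pools.steady_state(float(k[0]))
        n = _pool_sample_kernel(
            k, dt_s, pools.M, pools.x, pools.y, pools.l, pools.r,
            int(round(q0)), c0, w0, rel_steps, rel_q,
        )
    else:
        n = _poisson_sample_kernel(k, dt_s, rel_steps, rel_q)
    times = (rel_steps[:n] + rel_q[:n]) * dt_ms
    # the jitter of an event in the final step may not spill past the grid
    times = np.minimum(times, (k.size - 1) * dt_ms)
    return np.sort(times)
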