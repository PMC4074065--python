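"""Gene-expression dynamics model and per-target fitting kernels.

Each target gene x is modeled by saturable production under competition
between activating and inhibiting regulators, with first-order decay:

    dx/dt = v_max * (b + sum_A a_j u_j^h) / (1 + b + sum_A a_j u_j^h
            + sum_I c_j u_j^h) - d * x

where u_j(t) are the (linearly interpolated) observed regulator profiles,
a_j, c_j >= 0 are activation/inhibition weights, b >= 0 a basal drive,
v_max the production scale, d the decay rate and h a fixed Hill exponent.
The right-hand side is linear in x for given t, so a fixed-step RK4 on a
half-substep grid integrates it accurately and deterministically.

Fit quality is the variance-weighted mean squared error

    E = (1/T) * sum_t (x_sim(t) - x_obs(t))^2 / sigma_t^2

and a simulation is data-consistent when E < 0.75.

The heavy inner loops (integration and the bounded derivative-free local
search used for parameter fitting) are numba-compiled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "DynamicsModel",
    "FitResult",
    "ACCEPTANCE_THRESHOLD",
    "simulate",
    "weighted_error",
    "fit_subset",
    "variance_floor",
]

ACCEPTANCE_THRESHOLD = 0.75
#: default per-stage variance: (0.1 x dynamic range)^2 on [0,1]-scaled data
DEFAULT_VARIANCE = 0.01

# parameter bounds (log-space search): regulator weights, basal, v_max, decay.
# basal and v_max are capped so a regulator-free constant production cannot
# absorb strongly dynamic [0,1] profiles on its own.
_W_LO, _W_HI = 1e-3, 20.0
_B_LO, _B_HI = 1e-4, 0.5
_V_LO, _V_HI = 1e-3, 2.5
_D_LO, _D_HI = 1e-3, 5.0


@dataclass
class DynamicsModel:
    """A fitted single-target regulation model."""

    target: str
    activators: dict[str, float] = field(default_factory=dict)  # gene -> a_j
    inhibitors: dict[str, float] = field(default_factory=dict)  # gene -> c_j
    basal: float = 0.0
    v_max: float = 1.0
    decay: float = 1.0
    hill: float = 2.0

    def __post_init__(self) -> None:
        overlap = set(self.activators) & set(self.inhibitors)
        if overlap:
            raise ValueError(f"regulators both activating and inhibiting: {overlap}")

    @property
    def regulators(self) -> tuple[str, ...]:
        return tuple(self.activators) + tuple(self.inhibitors)


@dataclass
class FitResult:
    model: DynamicsModel
    error: float
    accepted: bool
    trajectory: np.ndarray


def variance_floor(profile: np.ndarray, frac: float = 0.1) -> float:
    """Variance floor (frac x dynamic range)^2; 0.01 on scaled rows."""
    rng = float(np.max(profile) - np.min(profile))
    return max((frac * rng) ** 2, 1e-12)


@njit(cache=True)
def _rk4_linear(prod_half: np.ndarray, d: float, x0: float,
                dts: np.ndarray) -> np.ndarray:
    """Integrate dx/dt = P(t) - d*x with P given on a half-step grid.

    prod_half has 2*n_steps + 1 entries (values at t, t+dt/2, t+dt for each
    step); dts the full step sizes.  Returns x at the n_steps+1 knots.
    """
    n_steps = dts.shape[0]
    out = np.empty(n_steps + 1)
    out[0] = x0
    x = x0
    for i in range(n_steps):
        dt = dts[i]
        p0 = prod_half[2 * i]
        pm = prod_half[2 * i + 1]
        p1 = prod_half[2 * i + 2]
        k1 = p0 - d * x
        k2 = pm - d * (x + 0.5 * dt * k1)
        k3 = pm - d * (x + 0.5 * dt * k2)
        k4 = p1 - d * (x + dt * k3)
        x = x + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        out[i + 1] = x
    return out


@njit(cache=True)
def _production(ua: np.ndarray, ui: np.ndarray, a: np.ndarray, c: np.ndarray,
                b: float, v: float) -> np.ndarray:
    """Production rate on the half grid. ua: (m_a, n_half), ui: (m_i, n_half)."""
    n = ua.shape[1] if ua.shape[0] > 0 else ui.shape[1]
    num = np.full(n, b)
    den = np.full(n, 1.0 + b)
    for j in range(ua.shape[0]):
        for t in range(n):
            num[t] += a[j] * ua[j, t]
            den[t] += a[j] * ua[j, t]
    for j in range(ui.shape[0]):
        for t in range(n):
            den[t] += c[j] * ui[j, t]
    return v * num / den


@njit(cache=True)
def _wmse(ua: np.ndarray, ui: np.ndarray, params: np.ndarray, x0: float,
          dts: np.ndarray, stage_idx: np.ndarray, obs: np.ndarray,
          variances: np.ndarray) -> float:
    m_a = ua.shape[0]
    m_i = ui.shape[0]
    a = params[:m_a]
    c = params[m_a:m_a + m_i]
    b = params[m_a + m_i]
    v = params[m_a + m_i + 1]
    d = params[m_a + m_i + 2]
    prod = _production(ua, ui, a, c, b, v)
    x = _rk4_linear(prod, d, x0, dts)
    err = 0.0
    for k in range(stage_idx.shape[0]):
        r = x[stage_idx[k]] - obs[k]
        err += r * r / variances[k]
    err /= stage_idx.shape[0]
    if not np.isfinite(err):
        return 1e18
    return err


@njit(cache=True)
def _fit_kernel(ua: np.ndarray, ui: np.ndarray, x0: float, dts: np.ndarray,
                stage_idx: np.ndarray, obs: np.ndarray, variances: np.ndarray,
                lo: np.ndarray, hi: np.ndarray, n_starts: int, n_iter: int,
                early_stop: float, seed: int) -> tuple[np.ndarray, float]:
    """Bounded derivative-free local search from random starts (log-space).

    Random restarts draw log-uniform parameters within bounds; each start
    then runs a shrinking-step coordinate random walk, accepting only
    improvements.  Stops early once the error falls below early_stop.
    """
    np.random.seed(seed)
    n_par = lo.shape[0]
    log_lo = np.log(lo)
    log_hi = np.log(hi)
    best_p = np.empty(n_par)
    best_e = 1e18
    for _ in range(n_starts):
        p = np.empty(n_par)
        for j in range(n_par):
            p[j] = np.exp(log_lo[j] + np.random.random() * (log_hi[j] - log_lo[j]))
        e = _wmse(ua, ui, p, x0, dts, stage_idx, obs, variances)
        for it in range(n_iter):
            sigma = 1.5 * (1.0 - it / n_iter) + 0.1
            j = np.random.randint(0, n_par)
            old = p[j]
            cand = old * np.exp(sigma * np.random.normal())
            if cand < lo[j]:
                cand = lo[j]
            elif cand > hi[j]:
                cand = hi[j]
            p[j] = cand
            e_new = _wmse(ua, ui, p, x0, dts, stage_idx, obs, variances)
            if e_new < e:
                e = e_new
            else:
                p[j] = old
            if e < early_stop:
                break
        if e < best_e:
            best_e = e
            best_p = p.copy()
        if best_e < early_stop:
            break
    return best_p, best_e


def _half_grid(times: np.ndarray, substeps: int):
    """Half-resolution integration grid over arbitrary ordered times.

    Returns (half_times, dts, stage_idx): half_times has 2*n_steps+1 knots,
    dts the full step per RK4 step, stage_idx the full-knot index of each
    observation time.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing, length >= 2")
    full = [times[0]]
    stage_idx = [0]
    for i in range(len(times) - 1):
        seg = np.linspace(times[i], times[i + 1], substeps + 1)[1:]
        full.extend(seg)
        stage_idx.append(len(full) - 1)
    full = np.asarray(full)
    dts = np.diff(full)
    half = np.empty(2 * len(dts) + 1)
    half[::2] = full
    half[1::2] = full[:-1] + dts / 2
    return half, dts, np.asarray(stage_idx, dtype=np.int64)


def _interp_pow(profiles: np.ndarray, times: np.ndarray, half_times: np.ndarray,
                hill: float) -> np.ndarray:
    """Linear interpolation of regulator profiles onto the half grid, then ^h."""
    if profiles.shape[0] == 0:
        return np.empty((0, len(half_times)))
    out = np.empty((profiles.shape[0], len(half_times)))
    for j in range(profiles.shape[0]):
        out[j] = np.interp(half_times, times, profiles[j])
    return np.power(out, hill)


def simulate(
    model: DynamicsModel,
    initial: float,
    times: np.ndarray,
    regulator_profiles: dict[str, np.ndarray],
    substeps: int = 4,
) -> np.ndarray:
    """Simulate the target trajectory at the observation times.

    ``regulator_profiles`` maps regulator gene -> profile sampled at
    ``times``; profiles are linearly interpolated between observations.
    Raises if any regulator of the model lacks a profile.
    """
    half_t, dts, stage_idx = _half_grid(np.asarray(times, float), substeps)
    times = np.asarray(times, dtype=float)
    act = (np.vstack([regulator_profiles[g] for g in model.activators])
           if model.activators else np.empty((0, len(times))))
    inh = (np.vstack([regulator_profiles[g] for g in model.inhibitors])
           if model.inhibitors else np.empty((0, len(times))))
    ua = _interp_pow(act, times, half_t, model.hill)
    ui = _interp_pow(inh, times, half_t, model.hill)
    a = np.array(list(model.activators.values()), dtype=float)
    c = np.array(list(model.inhibitors.values()), dtype=float)
    prod = _production(ua, ui, a, c, float(model.basal), float(model.v_max))
    x = _rk4_linear(prod, float(model.decay), float(initial), dts)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("non-finite trajectory")
    return x[stage_idx]


def weighted_error(trajectory: np.ndarray, observed: np.ndarray,
                   variances: np.ndarray | float) -> float:
    """Variance-weighted mean squared error between simulation and data."""
    trajectory = np.asarray(trajectory, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if trajectory.shape != observed.shape:
        raise ValueError("trajectory/observed length mismatch")
    var = np.broadcast_to(np.asarray(variances, dtype=float), observed.shape).copy()
    if np.any(var <= 0):
        var[var <= 0] = DEFAULT_VARIANCE
    return float(np.mean((trajectory - observed) ** 2 / var))


def fit_subset(
    target: str,
    observed: np.ndarray,
    times: np.ndarray,
    activator_profiles: np.ndarray,
    inhibitor_profiles: np.ndarray,
    *,
    variances: np.ndarray | float = DEFAULT_VARIANCE,
    hill: float = 2.0,
    substeps: int = 4,
    n_starts: int = 3,
    n_iter: int = 120,
    early_stop: float = ACCEPTANCE_THRESHOLD,
    seed: int = 0,
    param_bounds: dict | None = None,
) -> tuple[np.ndarray, float]:
    """Fit (a..., c..., b, v_max, d) for one regulator subset.

    activator_profiles / inhibitor_profiles are (m, T) arrays sampled at
    ``times``.  ``param_bounds`` may override individual box bounds
    (keys: b_lo, b_hi, v_lo, v_hi, d_lo, d_hi, w_lo, w_hi).  Returns the
    parameter vector and its weighted error.
    """
    times = np.asarray(times, dtype=float)
    observed = np.asarray(observed, dtype=float)
    half_t, dts, stage_idx = _half_grid(times, substeps)
    ua = _interp_pow(np.asarray(activator_profiles, float).reshape(-1, len(times)),
                     times, half_t, hill)
    ui = _interp_pow(np.asarray(inhibitor_profiles, float).reshape(-1, len(times)),
                     times, half_t, hill)
    m_a, m_i = ua.shape[0], ui.shape[0]
    pb = param_bounds or {}
    w_lo, w_hi = pb.get("w_lo", _W_LO), pb.get("w_hi", _W_HI)
    lo = np.concatenate([np.full(m_a, w_lo), np.full(m_i, w_lo),
                         [pb.get("b_lo", _B_LO), pb.get("v_lo", _V_LO),
                          pb.get("d_lo", _D_LO)]])
    hi = np.concatenate([np.full(m_a, w_hi), np.full(m_i, w_hi),
                         [pb.get("b_hi", _B_HI), pb.get("v_hi", _V_HI),
                          pb.get("d_hi", _D_HI)]])
    var = np.broadcast_to(np.asarray(variances, dtype=float), observed.shape)
    params, err = _fit_kernel(
        ua, ui, float(observed[0]), dts, stage_idx, observed,
        np.ascontiguousarray(var, dtype=float), lo, hi,
        n_starts, n_iter, early_stop, seed & 0x7FFFFFFF,
    )
    return params, float(err)
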