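"""Maximum-likelihood fitting of the NRL and WAM models, one learning set at a time.

Free parameters per set: a learning rate for every day (plus, for WAM,
per-day decision weights on the simplex) and a single inverse temperature
``beta in [0, 30]`` shared across the set's days.  Because values carry over
day boundaries, the per-day parameters are coupled; the whole set is therefore
fit *jointly*: an exhaustive search over a thin parameter grid picks the
starting point, and a constrained quasi-Newton optimizer (L-BFGS-B) refines
all parameters together.  The simplex constraint is handled by a smooth
bijection onto the simplex interior (two free log-ratio coordinates per day),
so the optimizer itself only sees box bounds.

The likelihood of a parameter vector factorizes per trial:
``ln L = sum_t ln P_t(chosen_t)`` with ``P_t`` the logistic of the decision
index, replayed from zero initial values through the recorded choices.  The
value trajectory depends only on the learning rates, so weight/beta candidates
are scored by vectorized numpy once the trajectory is replayed
(:mod:`plusmaze._replay`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import minimize

from ._replay import (
    SetArrays,
    loglik_from_index,
    nrl_value_diffs,
    per_day_loglik_from_index,
    wam_value_diffs,
)
from .exceptions import ConfigError, ParameterError
from .models import (
    BETA_MAX,
    DayParams,
    DecisionWeights,
    SetParams,
    _check_chronology,
)
from .task import TrialRecord

_Z_BOUND = 12.0  # log-ratio bound; keeps weights ~3e-6 away from the simplex edge
_W_EPS = 1e-5


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs for grid initialization and the joint optimizer.

    Defaults: a thin grid with steps of 0.05 on the learning rate, 1.0 on the
    inverse temperature and 0.1 on the weight-simplex lattice (the same
    (alpha, weights) grid point is used for every day to keep the search
    tractable; the optimizer then decouples the days).  Five seeded random
    restarts supplement the grid start to guard against local maxima.
    """

    grid_alpha_step: float = 0.05
    grid_beta_step: float = 1.0
    grid_weight_step: float = 0.1
    beta_bounds: tuple[float, float] = (0.0, BETA_MAX)
    decay: float = 1.0
    tol: float = 1e-8
    max_iter: int = 400
    n_restarts: int = 5
    restart_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.grid_alpha_step, self.grid_beta_step, self.grid_weight_step) <= 0:
            raise ConfigError("grid steps must be positive")
        if self.beta_bounds[0] >= self.beta_bounds[1]:
            raise ConfigError("beta bounds must be ordered")
        if not 0.0 <= self.decay <= 1.0:
            raise ConfigError("decay must be in [0, 1]")


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one model to one set's log."""

    set_label: str
    model_kind: str
    set_params: SetParams
    log_likelihood: float
    per_day_ll: tuple[float, ...]
    converged: bool
    n_trials: int
    beta_at_bound: bool = False

    def day_weights(self) -> np.ndarray | None:
        """Fitted per-day weight matrix (n_days, 3) for WAM, None for NRL."""
        if self.model_kind != "wam":
            return None
        return np.array([dp.weights.as_array() for dp in self.set_params.day_params])


def _alphas_of(set_params: SetParams, n_days: int) -> list[float]:
    return [set_params.day_params[d].alpha for d in range(n_days)]


def _wam_index(arrs: SetArrays, set_params: SetParams, decay: float) -> np.ndarray:
    diffs = wam_value_diffs(arrs, _alphas_of(set_params, arrs.n_days), decay)
    w = np.array(
        [set_params.day_params[d].weights.as_array() for d in range(arrs.n_days)]
    )
    return np.einsum("tj,tj->t", diffs, w[arrs.day0_arr])


def _trial_index(
    arrs: SetArrays, set_params: SetParams, model_kind: str, decay: float
) -> np.ndarray:
    if model_kind == "nrl":
        return nrl_value_diffs(arrs, _alphas_of(set_params, arrs.n_days), decay)
    if model_kind == "wam":
        for d in range(arrs.n_days):
            if set_params.day_params[d].weights is None:
                raise ParameterError(f"day {d + 1}: WAM fit requires decision weights")
        return _wam_index(arrs, set_params, decay)
    raise ParameterError(f"unknown model_kind {model_kind!r}")


def set_log_likelihood(
    log: Sequence[TrialRecord],
    set_params: SetParams,
    model_kind: Literal["nrl", "wam"],
    decay: float = 1.0,
) -> float:
    """Total log-likelihood of one set's observed choices under the model."""
    _check_chronology(log)
    arrs = SetArrays.from_records(log)
    if set_params.n_days < arrs.n_days:
        raise ParameterError("fewer day-parameter entries than days in the log")
    index = _trial_index(arrs, set_params, model_kind, decay)
    return loglik_from_index(index, arrs.sign, set_params.beta)


def per_day_log_likelihood(
    log: Sequence[TrialRecord],
    set_params: SetParams,
    model_kind: Literal["nrl", "wam"],
    decay: float = 1.0,
) -> np.ndarray:
    """Log-likelihood of each day's choices (summing to the set total)."""
    _check_chronology(log)
    arrs = SetArrays.from_records(log)
    index = _trial_index(arrs, set_params, model_kind, decay)
    return per_day_loglik_from_index(
        index, arrs.sign, arrs.day0_arr, arrs.n_days, set_params.beta
    )


# ---------------------------------------------------------------------------
# grid initialization


def simplex_lattice(step: float) -> list[tuple[float, float, float]]:
    """All weight triples on the simplex lattice with the given step.

    ``step`` must divide 1 (e.g. 0.1 gives 66 points).  Points are returned in
    ascending lexicographic order of (w_l, w_o, w_c).
    """
    k = round(1.0 / step)
    if abs(k * step - 1.0) > 1e-9 or k < 1:
        raise ConfigError(f"grid_weight_step {step} must divide 1")
    pts = []
    for i in range(k + 1):
        for j in range(k + 1 - i):
            pts.append((i / k, j / k, (k - i - j) / k))
    return pts


def _grid_axis(step: float, lo: float, hi: float) -> np.ndarray:
    n = int(math.floor((hi - lo) / step + 1e-9))
    return lo + step * np.arange(n + 1)


def grid_initialize(
    log: Sequence[TrialRecord],
    model_kind: Literal["nrl", "wam"],
    config: FitConfig | None = None,
) -> SetParams:
    """Exhaustive search over a thin grid; returns the best grid point.

    The same (alpha, weights) value is applied to every day of the set.  Ties
    are broken toward the lexicographically smaller parameter vector
    (alpha, w_l, w_o, w_c, beta), which the ascending scan order guarantees.
    """
    config = config or FitConfig()
    _check_chronology(log)
    arrs = SetArrays.from_records(log)
    alphas = _grid_axis(config.grid_alpha_step, 0.0, 1.0)
    betas = _grid_axis(config.grid_beta_step, *config.beta_bounds)
    if alphas.size == 0 or betas.size == 0:
        raise ConfigError("empty parameter grid")
    best_ll = -np.inf
    best: tuple[float, tuple[float, float, float] | None, float] | None = None
    if model_kind == "wam":
        lattice = np.array(simplex_lattice(config.grid_weight_step))  # (M, 3)
    for alpha in alphas:
        a = [float(alpha)] * arrs.n_days
        if model_kind == "nrl":
            d = nrl_value_diffs(arrs, a, config.decay)
            x = arrs.sign * d  # (n,)
            ll = -np.logaddexp(0.0, -np.outer(betas, x)).sum(axis=1)  # (B,)
            j = int(np.argmax(ll))
            if ll[j] > best_ll:
                best_ll = float(ll[j])
                best = (float(alpha), None, float(betas[j]))
        else:
            diffs = wam_value_diffs(arrs, a, config.decay)  # (n, 3)
            idx = (arrs.sign[:, None]) * (diffs @ lattice.T)  # (n, M)
            # (M, B) log-likelihood surface over weights x beta
            ll = -np.logaddexp(0.0, -idx[:, :, None] * betas[None, None, :]).sum(axis=0)
            flat = int(np.argmax(ll))
            if ll.flat[flat] > best_ll:
                m, j = divmod(flat, betas.size)
                best_ll = float(ll.flat[flat])
                best = (float(alpha), tuple(lattice[m]), float(betas[j]))
    alpha, w, beta = best
    weights = None if w is None else DecisionWeights(*w)
    day = DayParams(alpha=alpha, weights=weights)
    return SetParams(day_params=(day,) * arrs.n_days, beta=beta)


# ---------------------------------------------------------------------------
# joint constrained optimization


def _weights_to_z(w: DecisionWeights) -> tuple[float, float]:
    raw = np.clip(w.as_array(), _W_EPS, None)
    raw = raw / raw.sum()
    z1 = math.log(raw[1] / raw[0])
    z2 = math.log(raw[2] / raw[0])
    return (
        float(np.clip(z1, -_Z_BOUND, _Z_BOUND)),
        float(np.clip(z2, -_Z_BOUND, _Z_BOUND)),
    )


def _z_to_weights(z1: float, z2: float) -> tuple[float, float, float]:
    e1, e2 = math.exp(z1), math.exp(z2)
    denom = 1.0 + e1 + e2
    return (1.0 / denom, e1 / denom, e2 / denom)


class _Objective:
    """Negative set log-likelihood with a trajectory cache keyed on the alphas.

    The value trajectory depends only on the learning-rate vector, so when the
    optimizer perturbs weight or beta coordinates the replay is reused.
    """

    def __init__(self, arrs: SetArrays, model_kind: str, decay: float):
        self.arrs = arrs
        self.model_kind = model_kind
        self.decay = decay
        self._cache: dict[tuple[float, ...], np.ndarray] = {}

    def _diffs(self, alphas: tuple[float, ...]) -> np.ndarray:
        hit = self._cache.get(alphas)
        if hit is not None:
            return hit
        if len(self._cache) > 128:
            self._cache.clear()
        fn = nrl_value_diffs if self.model_kind == "nrl" else wam_value_diffs
        d = fn(self.arrs, alphas, self.decay)
        self._cache[alphas] = d
        return d

    def neg_ll(self, x: np.ndarray) -> float:
        n_days = self.arrs.n_days
        alphas = tuple(float(np.clip(a, 0.0, 1.0)) for a in x[:n_days])
        beta = float(np.clip(x[-1], 0.0, BETA_MAX))
        diffs = self._diffs(alphas)
        if self.model_kind == "nrl":
            index = diffs
        else:
            z = x[n_days : 3 * n_days]
            w = np.array(
                [_z_to_weights(z[2 * d], z[2 * d + 1]) for d in range(n_days)]
            )
            index = np.einsum("tj,tj->t", diffs, w[self.arrs.day0_arr])
        return -loglik_from_index(index, self.arrs.sign, beta)


def _encode(set_params: SetParams, model_kind: str, n_days: int) -> np.ndarray:
    alphas = [set_params.day_params[d].alpha for d in range(n_days)]
    if model_kind == "nrl":
        return np.array(alphas + [set_params.beta])
    zs: list[float] = []
    for d in range(n_days):
        zs.extend(_weights_to_z(set_params.day_params[d].weights))
    return np.array(alphas + zs + [set_params.beta])


def _decode(x: np.ndarray, model_kind: str, n_days: int) -> SetParams:
    beta = float(np.clip(x[-1], 0.0, BETA_MAX))
    days = []
    for d in range(n_days):
        alpha = float(np.clip(x[d], 0.0, 1.0))
        if model_kind == "nrl":
            days.append(DayParams(alpha=alpha))
        else:
            z1, z2 = x[n_days + 2 * d], x[n_days + 2 * d + 1]
            days.append(DayParams(alpha=alpha, weights=DecisionWeights(*_z_to_weights(z1, z2))))
    return SetParams(day_params=tuple(days), beta=beta)


def fit_set(
    log: Sequence[TrialRecord],
    model_kind: Literal["nrl", "wam"],
    config: FitConfig | None = None,
) -> FitResult:
    """Jointly fit all of a set's per-day parameters plus its beta by ML.

    Starts from the best thin-grid point plus ``config.n_restarts`` seeded
    random starts; the best final likelihood wins and is guaranteed to be at
    least the grid optimum's.  Optimizer failure is reported through
    ``converged=False`` with the best parameters found, never an exception.
    """
    config = config or FitConfig()
    _check_chronology(log)
    arrs = SetArrays.from_records(log)
    n_days = arrs.n_days
    grid_params = grid_initialize(log, model_kind, config)
    objective = _Objective(arrs, model_kind, config.decay)

    if model_kind == "nrl":
        bounds = [(0.0, 1.0)] * n_days + [config.beta_bounds]
    else:
        bounds = (
            [(0.0, 1.0)] * n_days
            + [(-_Z_BOUND, _Z_BOUND)] * (2 * n_days)
            + [config.beta_bounds]
        )

    rng = np.random.default_rng(config.restart_seed)
    starts = [_encode(grid_params, model_kind, n_days)]
    for _ in range(config.n_restarts):
        alphas = rng.uniform(0.0, 1.0, size=n_days)
        beta = rng.uniform(*config.beta_bounds)
        if model_kind == "nrl":
            starts.append(np.concatenate([alphas, [beta]]))
        else:
            zs = rng.normal(0.0, 2.0, size=2 * n_days)
            starts.append(np.concatenate([alphas, zs, [beta]]))

    best_x = starts[0]
    best_nll = objective.neg_ll(best_x)
    converged = False
    for x0 in starts:
        res = minimize(
            objective.neg_ll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_iter, "ftol": config.tol},
        )
        nll = objective.neg_ll(res.x)
        if nll < best_nll:
            best_nll, best_x = nll, res.x
            converged = bool(res.success)
        elif nll <= best_nll + 1e-12 and res.success:
            converged = True

    set_params = _decode(best_x, model_kind, n_days)
    per_day = per_day_log_likelihood(log, set_params, model_kind, config.decay)
    total = float(per_day.sum())
    beta_at_bound = (
        set_params.beta <= config.beta_bounds[0] + 1e-9
        or set_params.beta >= config.beta_bounds[1] - 1e-9
    )
    return FitResult(
        set_label=log[0].set_label,
        model_kind=model_kind,
        set_params=set_params,
        log_likelihood=total,
        per_day_ll=tuple(float(v) for v in per_day),
        converged=converged,
        n_trials=arrs.n,
        beta_at_bound=beta_at_bound,
    )
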