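"""Inverse identification of constitutive parameters from multi-rate tensile
curves via NSGA-II with Sobol-sequence design-of-experiments initialization.

Each loading rate contributes one objective: the RMS force error between the
candidate's simulated curve and the observed curve at that rate.  The
returned Pareto set is the non-dominated front of the final population; the
"best" member is the one minimizing the equally-weighted sum of the per-rate
RMSEs.

The NSGA-II core (fast non-dominated sorting, crowding distance, binary
tournament, simulated binary crossover, polynomial mutation) is implemented
here directly so the package has no optimizer dependency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import qmc

from .constitutive import MaterialParams
from .tensile import (ForceDisplacementCurve, LoadingProtocol, StripGeometry,
                      curve_rmse, simulate_tension)

__all__ = ["FitConfig", "FitResult", "sobol_doe", "nsga2_fit"]

PARAM_NAMES = ("alpha", "mu", "beta", "g_visc")

#: Wide default bounds bracketing the literature range with >= 2x margin.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (1.0, 60.0),
    "mu": (0.01, 10.0),    # MPa
    "beta": (0.01, 10.0),  # 1/s
    "g_visc": (0.01, 10.0),  # MPa
}

_PENALTY = 1e30  # fitness assigned to candidates with non-finite forces


@dataclass
class FitConfig:
    """Search-space bounds and NSGA-II settings."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS))
    pop_size: int = 100
    n_gen: int = 100
    seed: int = 0
    objective: str = "force"  # "force" (instrument space) or "stress"
    crossover_prob: float = 0.9
    eta_crossover: float = 15.0
    mutation_prob: float = 0.25  # 1 / n_vars
    eta_mutation: float = 20.0
    #: search the moduli/rate (mu, beta, G) on a log scale — their bounds
    #: span three decades, and the genetic operators behave far better on a
    #: well-scaled genotype.  alpha stays linear.
    log_scale: bool = True
    #: memetic local refinement: every `local_refine_every` generations a
    #: short Nelder-Mead burst is run from the current minimum-summed-RMSE
    #: member and the refined candidate is injected into the offspring pool.
    #: Pure SBX/polynomial-mutation NSGA-II stalls in the strongly
    #: ill-conditioned alpha-mu / beta-G valleys of this problem (the
    #: aggregate error plateaus ~4 decades above the attainable minimum);
    #: the hybrid keeps NSGA-II as the global driver while restoring the
    #: convergence depth needed for parameter recovery.  Set
    #: ``local_refine_every = 0`` for the canonical algorithm.
    local_refine_every: int = 5
    local_refine_budget: int = 150

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValueError(f"degenerate bounds for {name}: [{lo}, {hi}]")
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("population size must be >= 4 and even")
        if self.objective not in ("force", "stress"):
            raise ValueError("objective must be 'force' or 'stress'")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.bounds[n][0] for n in PARAM_NAMES])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.bounds[n][1] for n in PARAM_NAMES])


@dataclass
class FitResult:
    """Final Pareto set, the minimum-summed-RMSE member, and the trace of the
    generation-best summed RMSE."""

    pareto_set: list[tuple[MaterialParams, np.ndarray]]
    best: MaterialParams
    best_objectives: np.ndarray
    convergence: np.ndarray  # best summed RMSE per generation (incl. gen 0)
    n_evaluations: int

    @property
    def best_summed_rmse(self) -> float:
        return float(np.sum(self.best_objectives))


def _vec_to_params(x: np.ndarray, tissue: str = "") -> MaterialParams:
    return MaterialParams(alpha=float(x[0]), mu=float(x[1]),
                          beta=float(x[2]), g_visc=float(x[3]), tissue=tissue)


def _search_bounds(config: FitConfig) -> tuple[np.ndarray, np.ndarray]:
    """Bounds of the (possibly log-encoded) genotype space."""
    lo, hi = config.lower, config.upper
    if config.log_scale:
        lo, hi = lo.copy(), hi.copy()
        lo[1:] = np.log(lo[1:])
        hi[1:] = np.log(hi[1:])
    return lo, hi


def _decode(z: np.ndarray, config: FitConfig) -> np.ndarray:
    if not config.log_scale:
        return z
    x = np.array(z, dtype=float)
    x[..., 1:] = np.exp(x[..., 1:])
    return x


def sobol_doe(config: FitConfig, n: int) -> list[MaterialParams]:
    """Sample ``n`` parameter vectors from a scrambled Sobol sequence scaled
    to the bounds box (deterministic given ``config.seed``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z = _sobol_matrix(config, n)
    return [_vec_to_params(_decode(row, config)) for row in z]


def _sobol_matrix(config: FitConfig, n: int) -> np.ndarray:
    """Sobol points scaled to the genotype (search-space) box."""
    sampler = qmc.Sobol(d=len(PARAM_NAMES), scramble=True, seed=config.seed)
    # draw a full power-of-2 block (balance property) and keep the first n
    m = max(int(np.ceil(np.log2(n))), 0)
    unit = sampler.random_base2(m)[:n]
    lo, hi = _search_bounds(config)
    return qmc.scale(unit, lo, hi)


# --- NSGA-II primitives -----------------------------------------------------


def _domination_matrix(F: np.ndarray) -> np.ndarray:
    """dom[i, j] True iff candidate i dominates candidate j."""
    le = (F[:, None, :] <= F[None, :, :]).all(axis=-1)
    lt = (F[:, None, :] < F[None, :, :]).any(axis=-1)
    return le & lt


def fast_non_dominated_sort(F: np.ndarray) -> list[np.ndarray]:
    dom = _domination_matrix(F)
    n_dominators = dom.sum(axis=0)
    fronts: list[np.ndarray] = []
    remaining = np.ones(len(F), dtype=bool)
    while remaining.any():
        front = np.flatnonzero(remaining & (n_dominators == 0))
        if front.size == 0:  # numerical ties; dump the rest as one front
            front = np.flatnonzero(remaining)
        fronts.append(front)
        remaining[front] = False
        n_dominators = n_dominators - dom[front].sum(axis=0)
    return fronts


def crowding_distance(F: np.ndarray) -> np.ndarray:
    n, m = F.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return dist


def _sbx(parents: np.ndarray, lower: np.ndarray, upper: np.ndarray,
         prob: float, eta: float, rng: np.random.Generator) -> np.ndarray:
    """Simulated binary crossover on consecutive parent pairs."""
    children = parents.copy()
    n_pairs = len(parents) // 2
    for k in range(n_pairs):
        p1, p2 = parents[2 * k], parents[2 * k + 1]
        if rng.random() > prob:
            continue
        c1, c2 = p1.copy(), p2.copy()
        for j in range(parents.shape[1]):
            if rng.random() > 0.5 or abs(p1[j] - p2[j]) < 1e-14:
                continue
            u = rng.random()
            if u <= 0.5:
                beta_q = (2.0 * u) ** (1.0 / (eta + 1.0))
            else:
                beta_q = (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0))
            c1[j] = 0.5 * ((1 + beta_q) * p1[j] + (1 - beta_q) * p2[j])
            c2[j] = 0.5 * ((1 - beta_q) * p1[j] + (1 + beta_q) * p2[j])
        children[2 * k], children[2 * k + 1] = c1, c2
    return np.clip(children, lower, upper)


def _polynomial_mutation(X: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                         prob: float, eta: float,
                         rng: np.random.Generator) -> np.ndarray:
    Y = X.copy()
    span = upper - lower
    mutate = rng.random(X.shape) < prob
    u = rng.random(X.shape)
    delta_lo = (X - lower) / span
    delta_hi = (upper - X) / span
    exp = 1.0 / (eta + 1.0)
    low_branch = u < 0.5
    with np.errstate(invalid="ignore"):
        d_lo = (2 * u + (1 - 2 * u) * (1 - delta_lo) ** (eta + 1)) ** exp - 1.0
        d_hi = 1.0 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - delta_hi) ** (eta + 1)) ** exp
    delta = np.where(low_branch, d_lo, d_hi)
    Y = np.where(mutate, X + delta * span, X)
    return np.clip(Y, lower, upper)


def _nelder_mead_burst(fun, z0: np.ndarray, lower: np.ndarray,
                       upper: np.ndarray, budget: int) -> tuple[np.ndarray, int]:
    """Short bounded Nelder-Mead refinement; returns (point, evals used)."""
    from scipy.optimize import minimize as _minimize

    res = _minimize(fun, z0, method="Nelder-Mead",
                    options={"maxfev": budget, "xatol": 1e-12, "fatol": 1e-14})
    return np.clip(res.x, lower, upper), int(res.nfev)


def _tournament(rank: np.ndarray, crowd: np.ndarray, n: int,
                rng: np.random.Generator) -> np.ndarray:
    """Binary tournament with the crowded-comparison operator."""
    a = rng.integers(0, len(rank), n)
    b = rng.integers(0, len(rank), n)
    better_a = (rank[a] < rank[b]) | ((rank[a] == rank[b]) & (crowd[a] > crowd[b]))
    return np.where(better_a, a, b)


# --- objective evaluation ---------------------------------------------------


def _make_objective(observed: list[ForceDisplacementCurve],
                    geom: StripGeometry, mode: str):
    """Build a params-vector -> per-rate RMSE vector callable."""
    protocols = []
    for c in observed:
        dt = float(np.median(np.diff(c.time)))
        protocols.append(LoadingProtocol(rate=c.rate,
                                         max_displacement=float(c.displacement[-1]),
                                         dt=dt))
    if mode == "stress":
        # compare in stress space: divide forces by current area
        scale = [c.geometry.area0 / c.stretch for c in observed]
        observed = [c.with_force(c.force / s) for c, s in zip(observed, scale)]

    def evaluate(x: np.ndarray) -> np.ndarray:
        try:
            params = _vec_to_params(x)
        except ValueError:
            return np.full(len(observed), _PENALTY)
        out = np.empty(len(observed))
        with np.errstate(over="ignore", invalid="ignore"):
            for i, (obs, proto) in enumerate(zip(observed, protocols)):
                sim = simulate_tension(params, geom, proto)
                if mode == "stress":
                    sim = sim.with_force(sim.force / (geom.area0 / sim.stretch))
                if not np.all(np.isfinite(sim.force)):
                    out[i] = _PENALTY
                    continue
                out[i] = curve_rmse(sim, obs)
        out[~np.isfinite(out)] = _PENALTY
        return out

    return evaluate


def nsga2_fit(observed: list[ForceDisplacementCurve], geom: StripGeometry,
              config: FitConfig | None = None, tissue: str = "") -> FitResult:
    """Recover material parameters from observed tensile curves.

    Raises if ``observed`` is empty or if no candidate in the initial
    population yields finite forces.
    """
    if not observed:
        raise ValueError("need at least one observed curve")
    config = config or FitConfig()
    rng = np.random.default_rng(config.seed)
    lower, upper = _search_bounds(config)
    _evaluate_raw = _make_objective(list(observed), geom, config.objective)

    def evaluate(z: np.ndarray) -> np.ndarray:
        return _evaluate_raw(_decode(z, config))

    X = _sobol_matrix(config, config.pop_size)
    F = np.array([evaluate(x) for x in X])
    n_eval = len(X)
    if np.all(F >= _PENALTY):
        raise RuntimeError(
            "every initial candidate produced non-finite forces; "
            "check the parameter bounds against the loading amplitude")

    def best_index(Fm: np.ndarray) -> int:
        return int(np.argmin(Fm.sum(axis=1)))

    trace = [float(F.sum(axis=1).min())]
    for gen in range(config.n_gen):
        fronts = fast_non_dominated_sort(F)
        rank = np.empty(len(F), dtype=int)
        crowd = np.empty(len(F))
        for r, front in enumerate(fronts):
            rank[front] = r
            crowd[front] = crowding_distance(F[front])

        parents_idx = _tournament(rank, crowd, config.pop_size, rng)
        children = _sbx(X[parents_idx], lower, upper,
                        config.crossover_prob, config.eta_crossover, rng)
        children = _polynomial_mutation(children, lower, upper,
                                        config.mutation_prob, config.eta_mutation, rng)
        Fc = np.array([evaluate(x) for x in children])
        n_eval += len(children)

        if config.local_refine_every and gen % config.local_refine_every == 0:
            z0 = X[best_index(F)]
            refined, used = _nelder_mead_burst(
                lambda z: float(np.sum(evaluate(np.clip(z, lower, upper)))),
                z0, lower, upper, config.local_refine_budget)
            n_eval += used
            children = np.vstack([children, refined[np.newaxis]])
            Fc = np.vstack([Fc, evaluate(refined)[np.newaxis]])
            n_eval += 1

        # elitist environmental selection on parents + offspring
        X_all = np.vstack([X, children])
        F_all = np.vstack([F, Fc])
        fronts = fast_non_dominated_sort(F_all)
        keep: list[int] = []
        for front in fronts:
            if len(keep) + front.size <= config.pop_size:
                keep.extend(front.tolist())
            else:
                cd = crowding_distance(F_all[front])
                order = np.argsort(-cd, kind="stable")
                keep.extend(front[order][: config.pop_size - len(keep)].tolist())
                break
        keep_arr = np.array(keep)
        # guarantee the min-summed-RMSE member survives (monotone trace)
        overall_best = best_index(F_all)
        if overall_best not in keep:
            keep_arr[-1] = overall_best
        X, F = X_all[keep_arr], F_all[keep_arr]
        trace.append(float(F.sum(axis=1).min()))

    final_front = fast_non_dominated_sort(F)[0]
    pareto = [(_vec_to_params(_decode(X[i], config), tissue), F[i].copy())
              for i in final_front]
    i_best = best_index(F)
    return FitResult(pareto_set=pareto,
                     best=_vec_to_params(_decode(X[i_best], config), tissue),
                     best_objectives=F[i_best].copy(),
                     convergence=np.array(trace),
                     n_evaluations=n_eval)
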