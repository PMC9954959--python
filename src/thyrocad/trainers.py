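"""Trainers for the ANFIS parameter vector.

Three interchangeable optimizers, all minimizing training RMSE of the
continuous model output against 0/1 targets:

* :func:`train_ga` — the real-coded genetic algorithm (the method of
  interest).  Chromosome = flat parameter vector; fitness = RMSE;
  tournament selection, whole-arithmetic crossover, per-gene Gaussian
  mutation, elitism.
* :func:`train_bp` — full-batch gradient descent with momentum over all
  parameters, gradients computed analytically through the five network
  layers.
* :func:`train_hybrid` — per epoch, an exact least-squares solve of all
  consequent parameters (the output is linear in them once firing
  strengths are fixed) followed by one gradient step on the premises.

RMSE is computed on the continuous output, not on thresholded labels: the
fitness is regression-style, which gives the optimizers a smooth surface.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .fis_core import (
    SIGMA_FLOOR,
    AnfisModel,
    decode,
    encode,
    forward,
    forward_batch,
    parameter_count,
    split_params,
)

__all__ = [
    "GaConfig",
    "BpConfig",
    "TrainResult",
    "TrainingDiverged",
    "rmse",
    "train_ga",
    "train_bp",
    "train_hybrid",
    "random_search",
    "solve_consequents_ls",
    "gene_bounds",
    "rmse_gradient",
]

#: Ridge regularizer for the consequent least-squares solve.
LS_RIDGE = 1e-8

#: GA gene bounds on the scaled-input axis: centers may roam a little
#: outside [0, 1]; spreads stay positive and below twice the input range;
#: consequent coefficients get a generous symmetric box.
CENTER_BOUNDS = (-0.25, 1.25)
SIGMA_BOUNDS = (SIGMA_FLOOR, 2.0)
CONSEQUENT_BOUNDS = (-10.0, 10.0)


class TrainingDiverged(RuntimeError):
    """Raised when gradient training blows up (RMSE above 1e6)."""


@dataclass(frozen=True)
class GaConfig:
    """Genetic-algorithm control parameters.

    Defaults are the study settings: 100 iterations, population 50,
    crossover rate 0.4, mutation rate 0.15.
    """

    n_iterations: int = 100
    population_size: int = 50
    crossover_rate: float = 0.4
    mutation_rate: float = 0.15
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")


@dataclass(frozen=True)
class BpConfig:
    """Gradient-descent control parameters (shared by BP and hybrid).

    Defaults are the study settings: learning rate 0.2, momentum 0.4,
    100 iterations.
    """

    learning_rate: float = 0.2
    momentum: float = 0.4
    n_iterations: int = 100

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must lie in [0, 1)")


@dataclass(frozen=True)
class TrainResult:
    """Trained model plus the per-iteration fitness trace."""

    model: AnfisModel
    fitness_trace: np.ndarray
    final_rmse: float


def rmse(predicted: np.ndarray, actual: np.ndarray) -> float:
    """Root mean square error between two equal-length vectors."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {a.shape}")
    if p.size == 0:
        raise ValueError("rmse of empty vectors is undefined")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def gene_bounds(n_inputs: int, n_rules: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (lower, upper) arrays matching the chromosome layout."""
    n_total = parameter_count(n_inputs, n_rules)
    lo = np.empty(n_total)
    hi = np.empty(n_total)
    n_premise = 2 * n_inputs * n_rules
    # premise genes alternate (center, sigma)
    lo[:n_premise:2], hi[:n_premise:2] = CENTER_BOUNDS
    lo[1:n_premise:2], hi[1:n_premise:2] = SIGMA_BOUNDS
    lo[n_premise:], hi[n_premise:] = CONSEQUENT_BOUNDS
    return lo, hi


# ---------------------------------------------------------------------------
# genetic algorithm


def _box_feasible_template(
    model: AnfisModel, X: np.ndarray, y: np.ndarray,
    lo: np.ndarray, hi: np.ndarray,
) -> np.ndarray:
    """Project the initial model into the GA gene box without wrecking it.

    The near-unregularized least-squares consequents of the initialization
    can carry huge cancelling coefficients; clipping those to the gene box
    would destroy the starting fitness.  If any consequent gene falls
    outside the box, the consequents are re-solved with the smallest ridge
    on a fixed ladder whose solution fits, which trades a small amount of
    training RMSE for a feasible, well-conditioned chromosome.
    """
    vec = encode(model).values
    n_cons = model.n_rules * (model.n_inputs + 1)
    if np.all((vec >= lo) & (vec <= hi)):
        return vec
    for ridge in (1e-6, 1e-4, 1e-3, 1e-2, 1e-1, 1.0):
        cand = encode(solve_consequents_ls(model, X, y, ridge=ridge)).values
        if np.all((cand[-n_cons:] >= lo[-n_cons:]) & (cand[-n_cons:] <= hi[-n_cons:])):
            vec = cand
            break
    return np.clip(vec, lo, hi)


def _population_rmse(
    population: np.ndarray, n_inputs: int, n_rules: int,
    X: np.ndarray, y: np.ndarray,
) -> np.ndarray:
    preds = forward_batch(population, n_inputs, n_rules, X)
    return np.sqrt(np.mean((preds - y[None, :]) ** 2, axis=1))


def train_ga(
    data: np.ndarray,
    targets: np.ndarray,
    template_model: AnfisModel,
    cfg: GaConfig = GaConfig(),
) -> TrainResult:
    """Evolve the parameter vector with a real-coded GA.

    The initial population contains the template chromosome itself (so a
    template that is already optimal is never lost) plus Gaussian
    perturbations of it.  Each generation: the best ``elitism`` chromosomes
    carry over unchanged; parents are picked by tournaments of two; a
    fraction ``crossover_rate`` of parent pairs is blended by
    whole-arithmetic crossover (child = beta*p1 + (1-beta)*p2 with beta
    uniform on [0, 1]); every gene then mutates with probability
    ``mutation_rate`` by a Gaussian perturbation whose spread is a tenth of
    the gene's bound range.  Genes are clipped to their bounds throughout.
    """
    X = np.asarray(data, dtype=float)
    y = np.asarray(targets, dtype=float)
    n_in, n_ru = template_model.n_inputs, template_model.n_rules
    lo, hi = gene_bounds(n_in, n_ru)
    span = hi - lo
    rng = np.random.default_rng(cfg.seed)

    template = _box_feasible_template(template_model, X, y, lo, hi)
    pop = template[None, :] + rng.normal(
        0.0, 0.1 * span, size=(cfg.population_size, template.size)
    )
    pop[0] = template
    pop = np.clip(pop, lo, hi)

    best_vec = None
    best_fit = np.inf
    trace = np.empty(cfg.n_iterations)

    for it in range(cfg.n_iterations):
        fitness = _population_rmse(pop, n_in, n_ru, X, y)
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit:
            best_fit = float(fitness[gen_best])
            best_vec = pop[gen_best].copy()
        trace[it] = best_fit

        order = np.argsort(fitness, kind="stable")
        next_pop = np.empty_like(pop)
        next_pop[: cfg.elitism] = pop[order[: cfg.elitism]]

        n_children = cfg.population_size - cfg.elitism
        # tournament-2 selection for every parent slot
        cand = rng.integers(0, cfg.population_size, size=(n_children, 2, 2))
        parents = np.where(
            (fitness[cand[:, :, 0]] <= fitness[cand[:, :, 1]]),
            cand[:, :, 0],
            cand[:, :, 1],
        )                                                   # (n_children, 2)
        p1 = pop[parents[:, 0]]
        p2 = pop[parents[:, 1]]
        do_cross = rng.uniform(size=n_children) < cfg.crossover_rate
        beta = rng.uniform(size=(n_children, 1))
        children = np.where(do_cross[:, None], beta * p1 + (1 - beta) * p2, p1)

        mutate = rng.uniform(size=children.shape) < cfg.mutation_rate
        children = children + mutate * rng.normal(
            0.0, 0.1 * span, size=children.shape
        )
        next_pop[cfg.elitism:] = np.clip(children, lo, hi)
        pop = next_pop

    model = decode(best_vec, n_in, n_ru, template_model.input_scaling)
    return TrainResult(model=model, fitness_trace=trace, final_rmse=float(trace[-1]))


def random_search(
    data: np.ndarray,
    targets: np.ndarray,
    template_model: AnfisModel,
    n_evaluations: int,
    seed: int = 0,
    batch: int = 200,
) -> float:
    """Best RMSE over uniformly random chromosomes within the GA bounds.

    Baseline with the same evaluation budget as a GA run
    (population_size * n_iterations evaluations); used to check that the
    evolutionary operators actually contribute beyond blind sampling.
    """
    X = np.asarray(data, dtype=float)
    y = np.asarray(targets, dtype=float)
    n_in, n_ru = template_model.n_inputs, template_model.n_rules
    lo, hi = gene_bounds(n_in, n_ru)
    rng = np.random.default_rng(seed)
    best = np.inf
    remaining = n_evaluations
    while remaining > 0:
        k = min(batch, remaining)
        pop = rng.uniform(lo, hi, size=(k, lo.size))
        best = min(best, float(_population_rmse(pop, n_in, n_ru, X, y).min()))
        remaining -= k
    return best


# ---------------------------------------------------------------------------
# analytic gradients


def rmse_gradient(
    values: np.ndarray,
    n_inputs: int,
    n_rules: int,
    X: np.ndarray,
    y: np.ndarray,
) -> tuple[float, np.ndarray]:
    """RMSE and its gradient with respect to the flat parameter vector.

    Writing wbar for normalized firing strengths, f_ik for the rule
    outputs, y_k for the model output and e_k for the residual, the chain
    rule through the normalization gives

        d y_k / d log w_ik = wbar_ik (f_ik - y_k)
        d log w_ik / d c_ij = (x_kj - c_ij) / sigma_ij^2
        d log w_ik / d sigma_ij = (x_kj - c_ij)^2 / sigma_ij^3

    and the consequent derivatives are wbar_ik x_kj and wbar_ik.  The RMSE
    gradient is the residual-weighted sum of d y_k / d theta divided by
    (N * RMSE); at an exact fit the gradient is defined as zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    c, s, p, r = split_params(values, n_inputs, n_rules)
    s = np.maximum(s, SIGMA_FLOOR)

    diff = X[:, None, :] - c[None, :, :]                  # (N, R, n)
    z = diff / s[None, :, :]
    logw = -0.5 * np.sum(z * z, axis=2)                   # (N, R)
    wbar = np.exp(logw - logw.max(axis=1, keepdims=True))
    wbar /= wbar.sum(axis=1, keepdims=True)
    f = X @ p.T + r[None, :]                              # (N, R)
    pred = np.sum(wbar * f, axis=1)
    e = pred - y
    n = y.size
    err = float(np.sqrt(np.mean(e * e)))

    grad = np.zeros_like(values)
    if err == 0.0:
        return err, grad

    scale = 1.0 / (n * err)
    G = (e[:, None] * wbar) * (f - pred[:, None])         # dL/dlogw pre-factor
    grad_c = scale * np.einsum("nr,nrj->rj", G, diff / s[None, :, :] ** 2)
    grad_s = scale * np.einsum("nr,nrj->rj", G, diff**2 / s[None, :, :] ** 3)
    ew = e[:, None] * wbar
    grad_p = scale * np.einsum("nr,nj->rj", ew, X)
    grad_r = scale * ew.sum(axis=0)

    n_premise = 2 * n_inputs * n_rules
    grad[:n_premise] = np.stack([grad_c, grad_s], axis=2).ravel()
    grad[n_premise:] = np.concatenate([grad_p, grad_r[:, None]], axis=1).ravel()
    return err, grad


def _premise_mask(n_inputs: int, n_rules: int) -> np.ndarray:
    mask = np.zeros(parameter_count(n_inputs, n_rules), dtype=bool)
    mask[: 2 * n_inputs * n_rules] = True
    return mask


def train_bp(
    data: np.ndarray,
    targets: np.ndarray,
    template_model: AnfisModel,
    cfg: BpConfig = BpConfig(),
) -> TrainResult:
    """Full-batch gradient descent with momentum over all parameters.

    Update: v <- momentum*v - lr*grad; theta <- theta + v.  Spread genes
    are clamped to SIGMA_FLOOR after every step.
    """
    return _train_gradient(data, targets, template_model, cfg, premises_only=False)


def train_hybrid(
    data: np.ndarray,
    targets: np.ndarray,
    template_model: AnfisModel,
    cfg: BpConfig = BpConfig(),
) -> TrainResult:
    """Hybrid learning: exact consequent least squares + premise gradient.

    Each epoch first solves all consequent parameters exactly (ridge least
    squares on the firing-strength design matrix), then takes one momentum
    gradient step on the premise parameters only.
    """
    return _train_gradient(data, targets, template_model, cfg, premises_only=True)


def _train_gradient(
    data, targets, template_model: AnfisModel, cfg: BpConfig, premises_only: bool
) -> TrainResult:
    X = np.asarray(data, dtype=float)
    y = np.asarray(targets, dtype=float)
    n_in, n_ru = template_model.n_inputs, template_model.n_rules
    theta = encode(template_model).values.copy()
    vel = np.zeros_like(theta)
    premise = _premise_mask(n_in, n_ru)
    sigma_genes = np.zeros_like(premise)
    sigma_genes[1 : 2 * n_in * n_ru : 2] = True

    trace = np.empty(cfg.n_iterations)
    for it in range(cfg.n_iterations):
        if premises_only:
            model = decode(theta, n_in, n_ru, template_model.input_scaling)
            model = solve_consequents_ls(model, X, y)
            theta = encode(model).values.copy()
        err, grad = rmse_gradient(theta, n_in, n_ru, X, y)
        # descend on the mean squared error: same minimizers as RMSE, but
        # the gradient vanishes at an exact fit, so a constant step settles
        grad = 2.0 * err * grad
        if premises_only:
            grad = np.where(premise, grad, 0.0)
        vel = cfg.momentum * vel - cfg.learning_rate * grad
        theta = theta + vel
        theta[sigma_genes] = np.maximum(theta[sigma_genes], SIGMA_FLOOR)
        err_after, _ = rmse_gradient(theta, n_in, n_ru, X, y)
        if not np.isfinite(err_after) or err_after > 1e6:
            raise TrainingDiverged(
                f"RMSE {err_after:.3g} at iteration {it}; reduce the learning rate"
            )
        trace[it] = err_after

    model = decode(theta, n_in, n_ru, template_model.input_scaling)
    if premises_only:
        # close with the exact consequent solve for the final premises
        model = solve_consequents_ls(model, X, y)
        trace[-1] = rmse(forward(model, X), y)
    return TrainResult(
        model=model, fitness_trace=trace, final_rmse=float(trace[-1])
    )


# ---------------------------------------------------------------------------
# consequent least squares


def solve_consequents_ls(
    model: AnfisModel, data: np.ndarray, targets: np.ndarray,
    ridge: float = LS_RIDGE,
) -> AnfisModel:
    """Exact (ridge-stabilized) least-squares solve of all consequents.

    With premises fixed, the model output is linear in the consequent
    parameters: the design-matrix row for sample k concatenates, over rules
    i, the block  wbar_ik * [x_k, 1].  The normal equations are solved with
    a tiny ridge (1e-8) so rank-deficient designs (e.g. a rule that never
    fires) stay well-posed.
    """
    X = np.asarray(data, dtype=float)
    y = np.asarray(targets, dtype=float)
    vec = encode(model).values
    n_in, n_ru = model.n_inputs, model.n_rules

    c, s, _, _ = split_params(vec, n_in, n_ru)
    z = (X[:, None, :] - c[None, :, :]) / s[None, :, :]
    logw = -0.5 * np.sum(z * z, axis=2)
    wbar = np.exp(logw - logw.max(axis=1, keepdims=True))
    wbar /= wbar.sum(axis=1, keepdims=True)               # (N, R)

    ext = np.concatenate([X, np.ones((X.shape[0], 1))], axis=1)  # (N, n+1)
    Phi = (wbar[:, :, None] * ext[:, None, :]).reshape(X.shape[0], -1)
    A = Phi.T @ Phi + ridge * np.eye(Phi.shape[1])
    b = Phi.T @ y
    coef = np.linalg.solve(A, b)

    out = vec.copy()
    out[2 * n_in * n_ru :] = coef
    return decode(out, n_in, n_ru, model.input_scaling)
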