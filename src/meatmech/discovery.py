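"""Sparse constitutive model discovery by exhaustive subset fitting.

The eight-term free-energy library is fitted to one product's combined
tension / compression / shear mean curves by minimizing the per-mode
normalized mean squared error

    L = (1/n_ten) sum_i (P_ten(lam_i) - data_i)^2
      + (1/n_com) sum_i (P_com(lam_i) - data_i)^2
      + (1/n_shr) sum_i (P_shr(gam_i) - data_i)^2 .

For a fixed set of exponents the model stress is *linear* in the eight
linear weights, so every candidate is solved by non-negative linear least
squares (NNLS) on the per-mode-weighted design matrix. Subsets containing
exponential terms add an outer bounded search over their exponents with a
deterministic multi-start, NNLS profiling the linear weights at each trial
point. The contract is the loss minimum reached, not a particular
optimizer trajectory.

Best-in-class discovery enumerates the 8 one-term and 28 two-term subsets
(an L0-style sparsity device), collects the mean MSE of each in a
symmetric 8x8 error map (diagonal = one-term models), and reports the
lowest-error model of each cardinality, ties broken toward the
lexicographically smallest subset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, nnls

from .mechanics import (
    EXP_TERMS,
    ModelWeights,
    invariants_shear,
    invariants_uniaxial,
    piola_stress_shear,
    piola_stress_uniaxial,
)
from .preprocessing import MODES, ProductDataset

__all__ = [
    "TermSubset",
    "FitResult",
    "ErrorMap",
    "OptConfig",
    "combined_loss",
    "fit_subset",
    "sweep_best_in_class",
    "subset_count",
    "goodness_r2",
    "term_decomposition",
]

_EXP_SLOT = {2: 0, 4: 1, 6: 2, 8: 3}  # term index -> position in wexp


@dataclass(frozen=True)
class TermSubset:
    """An active subset of the eight library terms."""

    active: tuple[int, ...]

    def __init__(self, active) -> None:
        terms = tuple(sorted(set(int(k) for k in active)))
        if not terms or any(k < 1 or k > 8 for k in terms):
            raise ValueError("subset must be a non-empty subset of {1..8}")
        object.__setattr__(self, "active", terms)

    @property
    def exponential(self) -> tuple[int, ...]:
        return tuple(k for k in self.active if k in EXP_TERMS)

    def __iter__(self):
        return iter(self.active)

    def __len__(self):
        return len(self.active)


@dataclass
class OptConfig:
    """Settings for the exponent search of exponential subsets."""

    n_starts: int = 8
    seed: int = 0
    exp_lo: float = 1e-3
    exp_hi: float = 50.0  # also the overflow guard on exponent magnitude
    extra_starts: tuple = ()  # additional exponent start vectors


@dataclass
class FitResult:
    subset: TermSubset
    weights: ModelWeights
    mse_ten: float
    mse_com: float
    mse_shr: float
    r2: float
    converged: bool = True

    @property
    def mean_mse(self) -> float:
        return (self.mse_ten + self.mse_com + self.mse_shr) / 3.0

    @property
    def loss(self) -> float:
        return self.mse_ten + self.mse_com + self.mse_shr


@dataclass
class ErrorMap:
    """Symmetric 8x8 map of mean MSE: diagonal (i,i) holds the one-term
    model {i+1}, off-diagonal (i,j) the two-term model {i+1, j+1}."""

    matrix: np.ndarray
    fits: dict = field(default_factory=dict)


def subset_count(k: int) -> int:
    """Number of k-term subsets of the eight-term library, C(8, k)."""
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    return math.comb(8, k)


def _mode_states(ds: ProductDataset):
    """(invariants, geometric stress factors f1/f2, data, control) per mode."""
    out = {}
    for m in MODES:
        c = ds.curve(m)
        x = c.control_grid
        if m == "shear":
            inv = invariants_shear(x)
            f1 = f2 = 2.0 * x
        else:
            inv = invariants_uniaxial(x)
            f1 = 2.0 * (x - 1.0 / x**2)
            f2 = 2.0 * (1.0 - 1.0 / x**3)
        out[m] = (inv, f1, f2, c.mean_stress)
    return out


def _term_basis(k: int, inv, f1, f2, wexp) -> np.ndarray:
    """Stress contribution of term k per unit linear weight (exact chain rule)."""
    x1 = inv.I1 - 3.0
    x2 = inv.I2 - 3.0
    if k == 1:
        return f1 * np.ones_like(x1)
    if k == 2:
        e = wexp[0]
        return f1 * e * np.exp(e * x1)
    if k == 3:
        return f1 * 2.0 * x1
    if k == 4:
        e = wexp[1]
        return f1 * 2.0 * x1 * e * np.exp(e * x1**2)
    if k == 5:
        return f2 * np.ones_like(x2)
    if k == 6:
        e = wexp[2]
        return f2 * e * np.exp(e * x2)
    if k == 7:
        return f2 * 2.0 * x2
    if k == 8:
        e = wexp[3]
        return f2 * 2.0 * x2 * e * np.exp(e * x2**2)
    raise ValueError(f"term index {k} out of range")


def combined_loss(weights: ModelWeights, ds: ProductDataset) -> float:
    """Per-mode normalized squared-error loss L (kPa^2) of a weight vector."""
    L = 0.0
    for m in MODES:
        c = ds.curve(m)
        if m == "shear":
            model = piola_stress_shear(weights, c.control_grid, clip=True)
        else:
            model = piola_stress_uniaxial(weights, c.control_grid, clip=True)
        L += float(np.mean((model - c.mean_stress) ** 2))
    return L


def _design(ds_states, subset: TermSubset, wexp: np.ndarray):
    """Weighted design matrix and target for the concatenated three-mode fit.

    Rows of each mode are scaled by 1/sqrt(n_mode) so that the ordinary
    squared residual of the stacked system equals the per-mode normalized
    loss L.
    """
    cols, ys = [], []
    for m in MODES:
        inv, f1, f2, y = ds_states[m]
        scale = 1.0 / np.sqrt(y.size)
        cols.append(np.column_stack([_term_basis(k, inv, f1, f2, wexp) for k in subset]) * scale)
        ys.append(y * scale)
    return np.vstack(cols), np.concatenate(ys)


def _nnls_fit(ds_states, subset: TermSubset, wexp: np.ndarray):
    A, y = _design(ds_states, subset, wexp)
    w_sub, rnorm = nnls(A, y)
    return w_sub, rnorm**2


def _start_grid(cfg: OptConfig, ndim: int) -> list[np.ndarray]:
    """Deterministic multi-start points in exponent space (log-spaced grid
    plus seeded jitter), identical across runs for a fixed seed."""
    base = np.geomspace(0.05, 30.0, cfg.n_starts)
    rng = np.random.default_rng(cfg.seed)
    starts = []
    for i in range(cfg.n_starts):
        pt = np.full(ndim, base[i])
        if ndim > 1:
            pt = pt * rng.uniform(0.5, 2.0, size=ndim)
        starts.append(np.clip(pt, cfg.exp_lo, cfg.exp_hi))
    for extra in cfg.extra_starts:
        pt = np.asarray(extra, dtype=float)
        if pt.shape == (ndim,):
            starts.append(np.clip(pt, cfg.exp_lo, cfg.exp_hi))
    return starts


def fit_subset(ds: ProductDataset, subset, config: OptConfig | None = None) -> FitResult:
    """Best non-negative fit of one term subset to a product's mean curves.

    Purely linear subsets (terms 1, 3, 5, 7) are solved in closed form by
    NNLS. Subsets with exponential terms run a bounded multi-start search
    over the exponents with NNLS profiling of the linear weights.
    """
    subset = subset if isinstance(subset, TermSubset) else TermSubset(subset)
    cfg = config or OptConfig()
    states = _mode_states(ds)
    exp_terms = subset.exponential

    if not exp_terms:
        w_sub, _ = _nnls_fit(states, subset, np.zeros(4))
        best_exp = np.zeros(4)
        converged = True
    else:
        ndim = len(exp_terms)

        def objective(evec: np.ndarray) -> float:
            wexp = np.zeros(4)
            for e, k in zip(evec, exp_terms):
                wexp[_EXP_SLOT[k]] = e
            try:
                _, sse = _nnls_fit(states, subset, wexp)
            except (FloatingPointError, RuntimeError):
                return np.inf
            return sse

        best_val, best_vec, converged = np.inf, None, False
        bounds = [(cfg.exp_lo, cfg.exp_hi)] * ndim
        with np.errstate(over="raise"):
            for x0 in _start_grid(cfg, ndim):
                try:
                    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds)
                except FloatingPointError:
                    continue
                if np.isfinite(res.fun) and res.fun < best_val:
                    best_val, best_vec = res.fun, res.x
                    converged = True
        if best_vec is None:
            w = ModelWeights(w=np.zeros(8))
            return FitResult(subset, w, np.inf, np.inf, np.inf, r2=-np.inf, converged=False)
        best_exp = np.zeros(4)
        for e, k in zip(best_vec, exp_terms):
            best_exp[_EXP_SLOT[k]] = e
        w_sub, _ = _nnls_fit(states, subset, best_exp)

    w = np.zeros(8)
    for wi, k in zip(w_sub, subset):
        w[k - 1] = wi
    # zero-weight exponential terms leave their exponent irrelevant; keep it
    # anyway so the reported model is exactly the one that was evaluated
    weights = ModelWeights(w=w, wexp=best_exp)
    mses = _per_mode_mse(weights, ds)
    r2 = goodness_r2(weights, ds)["pooled"]
    return FitResult(subset, weights, mses["tension"], mses["compression"], mses["shear"], r2=r2, converged=converged)


def _model_curves(weights: ModelWeights, ds: ProductDataset) -> dict[str, np.ndarray]:
    out = {}
    for m in MODES:
        g = ds.curve(m).control_grid
        out[m] = (
            piola_stress_shear(weights, g, clip=True)
            if m == "shear"
            else piola_stress_uniaxial(weights, g, clip=True)
        )
    return out


def _per_mode_mse(weights: ModelWeights, ds: ProductDataset) -> dict[str, float]:
    model = _model_curves(weights, ds)
    return {m: float(np.mean((model[m] - ds.curve(m).mean_stress) ** 2)) for m in MODES}


def goodness_r2(weights_or_fit, ds: ProductDataset) -> dict[str, float]:
    """Pooled and per-mode coefficients of determination R^2 = 1 - SSres/SStot
    over the (concatenated) stress data."""
    weights = weights_or_fit.weights if isinstance(weights_or_fit, FitResult) else weights_or_fit
    model = _model_curves(weights, ds)
    out = {}
    res_all, dat_all = [], []
    for m in MODES:
        y = ds.curve(m).mean_stress
        r = model[m] - y
        res_all.append(r)
        dat_all.append(y)
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0.0:
            raise ValueError(f"zero-variance data in mode {m}; R^2 undefined")
        out[m] = 1.0 - float(np.sum(r**2)) / sst
    y = np.concatenate(dat_all)
    sst = float(np.sum((y - y.mean()) ** 2))
    out["pooled"] = 1.0 - float(np.sum(np.concatenate(res_all) ** 2)) / sst
    return out


def term_decomposition(fit: FitResult, ds: ProductDataset) -> dict[str, np.ndarray]:
    """Per-term additive stress contributions, shape (8, n_grid) per mode;
    rows sum to the total model stress pointwise."""
    states = _mode_states(ds)
    out = {}
    for m in MODES:
        inv, f1, f2, _ = states[m]
        rows = [fit.weights.w[k - 1] * _term_basis(k, inv, f1, f2, fit.weights.wexp) for k in range(1, 9)]
        out[m] = np.vstack(rows)
    return out


def sweep_best_in_class(ds: ProductDataset, config: OptConfig | None = None):
    """Fit all 8 one-term and 28 two-term models (36 fits) to one product.

    Returns ``(error_map, best_one_term, best_two_term)``. For two-term
    subsets, the optimal exponents found for the constituent one-term
    models seed extra starts, so adding a term can never worsen the
    reachable minimum. Ties in the best-model selection go to the
    lexicographically smallest subset.
    """
    cfg = config or OptConfig()
    M = np.full((8, 8), np.nan)
    fits: dict[tuple[int, ...], FitResult] = {}

    one_exp: dict[int, float] = {}
    for k in range(1, 9):
        fit = fit_subset(ds, TermSubset((k,)), cfg)
        fits[(k,)] = fit
        M[k - 1, k - 1] = fit.mean_mse
        if k in EXP_TERMS:
            one_exp[k] = float(fit.weights.wexp[_EXP_SLOT[k]])

    for i, j in itertools.combinations(range(1, 9), 2):
        sub = TermSubset((i, j))
        extra = []
        if sub.exponential:
            extra.append([one_exp.get(k, 1.0) for k in sub.exponential])
        pair_cfg = OptConfig(
            n_starts=cfg.n_starts,
            seed=cfg.seed,
            exp_lo=cfg.exp_lo,
            exp_hi=cfg.exp_hi,
            extra_starts=tuple(tuple(e) for e in extra) + cfg.extra_starts,
        )
        fit = fit_subset(ds, sub, pair_cfg)
        fits[(i, j)] = fit
        M[i - 1, j - 1] = M[j - 1, i - 1] = fit.mean_mse

    ones = sorted((k,) for k in range(1, 9))
    twos = sorted(itertools.combinations(range(1, 9), 2))
    best_one = min(ones, key=lambda s: (fits[s].mean_mse, s))
    best_two = min(twos, key=lambda s: (fits[s].mean_mse, s))
    return ErrorMap(matrix=M, fits=fits), fits[best_one], fits[best_two]
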