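"""Monte Carlo comparison of the estimators under controlled collinearity.

The experiment generates p regressor columns sharing a common latent factor,

    x_ij = sqrt(1 - rho^2) w_ij + rho w_{i,p+1},    w ~ iid N(0, 1),

so each column has unit variance and every pair of columns has correlation
rho^2.  True slopes are equal with unit squared norm (beta_j = 1/sqrt(p));
the intercept beta_0 in {-1, 0, 1} sets the average intensity of the
counts.  Responses are drawn as y_i ~ Poisson(exp(x_i' beta)).  Each
replication refits the model, applies every selection rule and estimator,
and accumulates the squared coefficient error; a cell's estimated risk is

    MSE(b) = (1/R) sum_r || b_r - beta ||^2

over R replications, reported with its Monte Carlo standard error.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .poisson_core import CountDataset, FitError, fit_pmle, spectral, weighted_crossproduct
from .shrinkage import ESTIMATOR_NAMES, all_estimates

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationCell",
    "gen_design",
    "make_beta",
    "gen_response",
    "estimated_mse",
    "run_cell",
    "run_table",
    "default_grid",
    "to_wide",
    "plot_mse_vs_n",
]

ETA_GUARD = 30.0  # linear predictors beyond this are pathological draws

DEFAULT_NS = (50, 75, 100, 200)
DEFAULT_PS = (4, 7)
DEFAULT_RHOS = (0.8, 0.9, 0.95, 0.99, 0.999)
DEFAULT_INTERCEPTS = (-1, 0, 1)


@dataclass
class SimulationConfig:
    """One (n, p, rho, intercept) cell of the experiment."""

    n: int = 100
    p: int = 4
    rho: float = 0.9
    intercept: float = 0.0
    reps: int = 1000
    seed: int = 12345
    weight_convention: str = "mu"
    estimators: tuple[str, ...] = ESTIMATOR_NAMES
    fix_design: bool = False
    mse_excludes_intercept: bool = False

    def __post_init__(self) -> None:
        if self.n <= self.p + 1:
            raise ValueError("need n > p+1")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must lie in [0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class SimulationCell:
    """Estimated risks for one configuration."""

    config: SimulationConfig
    mse_by_estimator: dict[str, float]
    mc_se: dict[str, float]
    n_failed: int
    valid: bool
    sq_errors: np.ndarray = field(repr=False)  # reps x n_estimators
    estimator_order: tuple[str, ...] = ESTIMATOR_NAMES


def gen_design(n: int, p: int, rho: float, seed) -> np.ndarray:
    """Generate the n x p collinear regressor matrix (no intercept column).

    ``seed`` may be an int, a SeedSequence, or a Generator.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    w = rng.standard_normal((n, p + 1))
    return np.sqrt(1.0 - rho**2) * w[:, :p] + rho * w[:, [p]]


def make_beta(p: int, intercept: float) -> np.ndarray:
    """True coefficients: element 0 is the intercept, slopes all 1/sqrt(p)."""
    beta = np.full(p + 1, 1.0 / math.sqrt(p))
    beta[0] = intercept
    return beta


def gen_response(X: np.ndarray, beta: np.ndarray, seed, eta_guard: float = ETA_GUARD) -> np.ndarray:
    """Draw y_i ~ Poisson(exp(x_i' beta)) for a design with intercept column."""
    eta = X @ beta
    if np.any(eta > eta_guard):
        raise OverflowError(
            f"linear predictor exceeds {eta_guard} (max {eta.max():.2f}): pathological draw"
        )
    rng = np.random.default_rng(seed)
    return rng.poisson(np.exp(eta)).astype(float)


def estimated_mse(estimates: np.ndarray, truth: np.ndarray) -> float:
    """Mean over replications of the squared Euclidean error."""
    estimates = np.atleast_2d(np.asarray(estimates, dtype=float))
    diff = estimates - np.asarray(truth, dtype=float)[None, :]
    return float(np.mean(np.sum(diff**2, axis=1)))


def _one_replication(cfg: SimulationConfig, beta: np.ndarray, rep_seed,
                     Xfixed: np.ndarray | None) -> np.ndarray | None:
    """Squared errors for one replication, or None if the draw/fit failed."""
    ss = rep_seed.spawn(2)
    if Xfixed is None:
        Xr = gen_design(cfg.n, cfg.p, cfg.rho, ss[0])
        X = np.column_stack([np.ones(cfg.n), Xr])
    else:
        X = Xfixed
    try:
        y = gen_response(X, beta, ss[1])
        data = CountDataset(X, y)
        fit = fit_pmle(data, weight_convention=cfg.weight_convention)
        if not fit.converged:
            return None
        G = weighted_crossproduct(data, fit)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            spec = spectral(G, fit)
            estimates = all_estimates(fit, spec)
    except (OverflowError, FitError, ValueError):
        return None
    sl = slice(1, None) if cfg.mse_excludes_intercept else slice(None)
    return np.array(
        [np.sum((estimates[name].beta[sl] - beta[sl]) ** 2) for name in cfg.estimators]
    )


def run_cell(config: SimulationConfig) -> SimulationCell:
    """Run one cell: fresh design + response per replication, all estimators.

    Non-converged or pathological replications are re-drawn (logged) up to a
    5% budget; beyond that the cell is flagged invalid.
    """
    cfg = config
    beta = make_beta(cfg.p, cfg.intercept)
    budget = math.ceil(0.05 * cfg.reps)
    master = np.random.SeedSequence(cfg.seed)
    streams = iter(master.spawn(cfg.reps + budget))
    Xfixed = None
    if cfg.fix_design:
        Xr = gen_design(cfg.n, cfg.p, cfg.rho, master.spawn(1)[0])
        Xfixed = np.column_stack([np.ones(cfg.n), Xr])

    rows: list[np.ndarray] = []
    n_failed = 0
    while len(rows) < cfg.reps:
        try:
            stream = next(streams)
        except StopIteration:
            break
        result = _one_replication(cfg, beta, stream, Xfixed)
        if result is None:
            n_failed += 1
            logger.debug("replication failed (n_failed=%d), re-drawing", n_failed)
            continue
        rows.append(result)

    valid = len(rows) == cfg.reps and n_failed <= budget
    sq = np.array(rows) if rows else np.empty((0, len(cfg.estimators)))
    mse = {name: float(np.mean(sq[:, j])) for j, name in enumerate(cfg.estimators)}
    mc_se = {
        name: float(np.std(sq[:, j], ddof=1) / math.sqrt(len(rows))) if len(rows) > 1 else float("nan")
        for j, name in enumerate(cfg.estimators)
    }
    if not valid:
        logger.warning("cell %s invalid: %d failed replications (budget %d)", cfg, n_failed, budget)
    return SimulationCell(
        config=cfg, mse_by_estimator=mse, mc_se=mc_se,
        n_failed=n_failed, valid=valid, sq_errors=sq, estimator_order=tuple(cfg.estimators),
    )


def default_grid(
    master_seed: int,
    ns=DEFAULT_NS,
    ps=DEFAULT_PS,
    rhos=DEFAULT_RHOS,
    intercepts=DEFAULT_INTERCEPTS,
    reps: int = 1000,
    **kwargs,
) -> list[SimulationConfig]:
    """The full experimental grid, one reproducible child seed per cell."""
    cells = [
        (intercept, p, n, rho)
        for intercept in intercepts
        for p in ps
        for n in ns
        for rho in rhos
    ]
    children = np.random.SeedSequence(master_seed).spawn(len(cells))
    return [
        SimulationConfig(
            n=n, p=p, rho=rho, intercept=intercept, reps=reps,
            seed=int(child.generate_state(1)[0] % (2**31)), **kwargs,
        )
        for (intercept, p, n, rho), child in zip(cells, children)
    ]


def run_table(grid: list[SimulationConfig]) -> pd.DataFrame:
    """Run every cell of a grid; long-format results table.

    Columns: intercept, p, n, rho, estimator, mse, mc_se, n_failed, valid.
    """
    records = []
    for cfg in grid:
        cell = run_cell(cfg)
        for name in cell.estimator_order:
            records.append(
                dict(
                    intercept=cfg.intercept, p=cfg.p, n=cfg.n, rho=cfg.rho,
                    estimator=name, mse=cell.mse_by_estimator[name],
                    mc_se=cell.mc_se[name], n_failed=cell.n_failed, valid=cell.valid,
                )
            )
    return pd.DataFrame.from_records(records)


def to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long table into the column order PKLE1, PKLE2, PLE, PRRE, PMLE."""
    wide = long.pivot_table(
        index=["intercept", "p", "n", "rho"], columns="estimator", values="mse"
    ).reset_index()
    cols = ["intercept", "p", "n", "rho"] + [c for c in ("PKLE1", "PKLE2", "PLE", "PRRE", "PMLE") if c in wide]
    return wide[cols]


def plot_mse_vs_n(long: pd.DataFrame, intercept: float, p: int, rho: float, path: str) -> None:
    """Line plot of estimated MSE against sample size for one (intercept, p, rho)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = long[(long.intercept == intercept) & (long.p == p) & (long.rho == rho)]
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, grp in sub.groupby("estimator"):
        grp = grp.sort_values("n")
        ax.plot(grp.n, grp.mse, marker="o", label=name)
    ax.set_xlabel("sample size n")
    ax.set_ylabel("estimated MSE")
    ax.set_title(f"intercept={intercept}, p={p}, rho={rho}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
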