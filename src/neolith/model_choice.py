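"""ABC rejection over demographic models, posterior summaries, a
simulation-based likelihood, AIC, and Akaike weights.

The rejection step samples each model's priors uniformly, simulates the
five-F_ST summary vector, and retains the simulations closest (unweighted
Euclidean distance) to the observed vector.  Model fit is then scored by
re-simulating at the best-fitting parameter values and evaluating a
product-Gaussian kernel density estimate of the simulated summary cloud at
the observed point; AIC = 2k - 2 lnL and Akaike weights
w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) compare the models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import ModelSpec, simulate_summary

logger = logging.getLogger(__name__)

_STAT_COLS = ["HG_NE", "HG_CE", "LBK_NE", "LBK_CE", "LBK_HG"]


@dataclass
class AbcRun:
    """One rejection run: full simulation table plus the retained subset."""

    model_id: str
    n_sims: int
    retain: float
    seed: int
    table: pd.DataFrame  # params + summary stats + distance, all simulations
    retained: pd.DataFrame  # the ceil(retain * n_sims) closest rows
    n_failures: int = 0

    @property
    def best_params(self) -> dict[str, float]:
        """Parameter values of the minimum-distance retained simulation."""
        row = self.retained.iloc[0]
        return {p: float(row[p]) for p in self.param_names}

    @property
    def param_names(self) -> list[str]:
        return [c for c in self.table.columns
                if c not in _STAT_COLS and c != "distance"]


def run_abc(
    model: ModelSpec,
    observed: np.ndarray,
    n_sims: int,
    retain: float = 0.01,
    seed: int = 0,
    normalize: bool = False,
) -> AbcRun:
    """Rejection ABC: simulate ``n_sims`` parameter draws, keep the top
    ``retain`` fraction by Euclidean distance to ``observed``.

    With ``normalize=True`` each summary statistic is scaled by its
    simulated standard deviation before the distance is taken (off by
    default: raw F_ST values are compared directly).
    Failed simulations are logged, resampled, and counted.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    if not (0.0 < retain <= 1.0):
        raise ValueError("retain must be in (0, 1]")
    observed = np.asarray(observed, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    failures = 0
    while len(rows) < n_sims:
        params = model.sample_priors(rng)
        try:
            stats = simulate_summary(model, params, rng)
        except Exception as exc:  # resample on simulation failure
            failures += 1
            logger.warning("simulation failure under %s: %s", model.id, exc)
            if failures > 10 * n_sims:
                raise RuntimeError(f"too many simulation failures for {model.id}")
            continue
        rows.append(list(params.values()) + list(stats))
    param_names = list(model.priors)
    table = pd.DataFrame(rows, columns=param_names + _STAT_COLS)
    stats_mat = table[_STAT_COLS].to_numpy()
    scale = stats_mat.std(axis=0, ddof=1) if normalize else np.ones(len(_STAT_COLS))
    scale = np.where(scale > 0, scale, 1.0)
    table["distance"] = np.sqrt(
        (((stats_mat - observed) / scale) ** 2).sum(axis=1)
    )
    n_keep = int(np.ceil(retain * n_sims))
    retained = table.nsmallest(n_keep, "distance").reset_index(drop=True)
    return AbcRun(
        model_id=model.id, n_sims=n_sims, retain=retain, seed=seed,
        table=table, retained=retained, n_failures=failures,
    )


def posterior_summary(run: AbcRun, level: float = 0.90) -> pd.DataFrame:
    """Median, KDE mode, and central interval per parameter of the retained
    posterior sample."""
    from scipy.stats import gaussian_kde

    if run.retained.empty:
        raise ValueError("retained set is empty")
    alpha = (1.0 - level) / 2.0
    rows = []
    for p in run.param_names:
        x = run.retained[p].to_numpy()
        if len(x) < 2 or np.std(x) == 0:
            mode = float(x[0])
        else:
            kde = gaussian_kde(x)
            grid = np.linspace(x.min(), x.max(), 512)
            mode = float(grid[np.argmax(kde(grid))])
        rows.append({
            "parameter": p,
            "median": float(np.median(x)),
            "mode": mode,
            "lower": float(np.quantile(x, alpha)),
            "upper": float(np.quantile(x, 1.0 - alpha)),
        })
    return pd.DataFrame(rows).set_index("parameter")


def estimate_lnL(
    model: ModelSpec,
    params: dict[str, float],
    observed: np.ndarray,
    n_reps: int = 1000,
    seed: int = 0,
) -> float:
    """Simulation-based log-likelihood of ``observed`` at fixed parameters.

    Simulates ``n_reps`` summary vectors and evaluates a product-Gaussian
    KDE (per-dimension Silverman bandwidth) at the observed point.  Returns
    ``-inf`` when the observed point has zero density under all kernels.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    observed = np.asarray(observed, dtype=float)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_reps, len(observed)))
    for i in range(n_reps):
        sims[i] = simulate_summary(model, params, rng)
    d = sims.shape[1]
    sigma = sims.std(axis=0, ddof=1)
    sigma = np.maximum(sigma, 1e-8)  # degenerate dimensions
    h = sigma * (4.0 / (d + 2.0)) ** (1.0 / (d + 4.0)) * n_reps ** (-1.0 / (d + 4.0))
    z = (observed[None, :] - sims) / h[None, :]
    log_kernels = -0.5 * (z**2).sum(axis=1) - np.log(h).sum() - 0.5 * d * np.log(
        2.0 * np.pi
    )
    m = log_kernels.max()
    if not np.isfinite(m):
        return float("-inf")
    return float(m + np.log(np.exp(log_kernels - m).mean()))


def aic(lnL: float, k: int) -> float:
    """Akaike information criterion: AIC = 2k - 2 lnL."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return 2.0 * k - 2.0 * lnL


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights from a vector of AIC values.

    w_i = exp(-Delta_i / 2) / sum_j exp(-Delta_j / 2), Delta_i relative to
    the best (smallest) AIC; invariant under adding a constant to all AICs.
    """
    values = np.asarray(aics, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("need at least one finite AIC")
    delta = values - values[finite].min()
    rel = np.where(finite, np.exp(-delta / 2.0), 0.0)
    return rel / rel.sum()


@dataclass
class ModelComparison:
    """Per-model fit table: free parameters k, lnL, AIC and Akaike weight."""

    table: pd.DataFrame  # index: model ids; columns k, lnL, AIC, weight
    provenance: dict = field(default_factory=dict)

    @property
    def best_model(self) -> str:
        return str(self.table["AIC"].idxmin())


def compare_models(
    models: list[ModelSpec],
    observed: np.ndarray,
    n_sims: int = 100_000,
    retain: float = 0.01,
    lnl_reps: int = 1000,
    seed: int = 0,
) -> ModelComparison:
    """Full pipeline: rejection ABC per model, maximum-likelihood point
    (minimum-distance retained draw), simulation-based lnL, AIC, weights."""
    seeds = np.random.SeedSequence(seed).generate_state(2 * len(models)) % (2**31)
    rows = []
    provenance = {"seed": seed, "n_sims": n_sims, "retain": retain,
                  "lnl_reps": lnl_reps, "per_model_seeds": {}}
    for i, model in enumerate(models):
        abc_seed, lnl_seed = int(seeds[2 * i]), int(seeds[2 * i + 1])
        run = run_abc(model, observed, n_sims=n_sims, retain=retain, seed=abc_seed)
        best = run.best_params
        lnl = estimate_lnL(model, best, observed, n_reps=lnl_reps, seed=lnl_seed)
        k = model.k_free_parameters
        rows.append({"model": model.id, "k": k, "lnL": lnl,
                     "AIC": aic(lnl, k), **{f"ml_{p}": v for p, v in best.items()}})
        provenance["per_model_seeds"][model.id] = (abc_seed, lnl_seed)
    table = pd.DataFrame(rows).set_index("model")
    table["weight"] = akaike_weights(table["AIC"].to_numpy())
    return ModelComparison(table=table, provenance=provenance)
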