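"""Shared-haplotype analysis against pooled modern population panels.

The query (an ancient sample) is matched by exact haplotype identity over
the trimmed HVS-I window against equal-size modern population pools.  Query
haplotypes are classified as *noninformative* (widespread: present in a
large fraction of pools), *informative* (limited geographic distribution),
or *unique* (absent from every pool); per-pool sharing percentages, a
two-proportion z test for pools with elevated sharing, and bootstrap
confidence intervals complete the pipeline.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .haplotypes import TRIMMED_WINDOW, PopulationSample


@dataclass
class PooledPanel:
    """Equal-size pools subsampled from source populations."""

    pools: list[PopulationSample]
    target_n: int
    seed: int
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.pools]


def pool_and_subsample(
    populations: list[PopulationSample],
    target_n: int = 500,
    seed: int = 0,
    min_size: int | None = None,
) -> PooledPanel:
    """Subsample every population to at most ``target_n`` members.

    Populations below ``min_size`` (default: ``target_n``, i.e. only pools
    reaching the target size participate) are excluded.  Subsampling is
    without replacement and deterministic given the seed.
    """
    if target_n < 1:
        raise ValueError("target_n must be >= 1")
    min_size = target_n if min_size is None else min_size
    rng = np.random.default_rng(seed)
    pools = []
    provenance: dict[str, str] = {}
    for pop in populations:
        if pop.size < min_size:
            continue
        if pop.size > target_n:
            idx = rng.choice(pop.size, size=target_n, replace=False)
            members = [pop.individuals[i] for i in sorted(idx)]
        else:
            members = list(pop.individuals)
        pools.append(
            PopulationSample(pop.name, members, pop.coordinates, pop.age_generations)
        )
        provenance[pop.name] = pop.name
    return PooledPanel(pools=pools, target_n=target_n, seed=seed,
                       provenance=provenance)


@dataclass
class PivotTable:
    """Haplotype-by-pool hit counts plus the query's own keys."""

    counts: pd.DataFrame  # rows: canonical keys; columns: pool names
    query_keys: list[str]  # distinct canonical keys of the query sample
    pool_sizes: pd.Series
    window: tuple[int, int]

    @property
    def presence(self) -> pd.DataFrame:
        return (self.counts > 0).astype(int)


def build_pivot(
    panel: PooledPanel,
    query: PopulationSample,
    window: tuple[int, int] = TRIMMED_WINDOW,
) -> PivotTable:
    """Exact-identity pivot of haplotype hit counts across the panel pools.

    Rows cover the union of panel and query haplotypes (trimmed to the
    common window); query haplotypes absent everywhere get all-zero rows.
    """
    pool_counts = {p.name: Counter(p.canonical_keys(window)) for p in panel.pools}
    query_keys = sorted(set(query.canonical_keys(window)))
    all_keys = sorted(set().union(*pool_counts.values(), query_keys))
    counts = pd.DataFrame(
        {name: [c.get(k, 0) for k in all_keys] for name, c in pool_counts.items()},
        index=all_keys, dtype=int,
    )
    sizes = pd.Series({p.name: len(p.canonical_keys(window)) for p in panel.pools})
    return PivotTable(counts=counts, query_keys=query_keys, pool_sizes=sizes,
                      window=window)


@dataclass
class HaplotypeClassification:
    """Partition of the query haplotypes by modern-day distribution."""

    noninformative: list[str]
    informative: list[str]
    unique: list[str]
    widespread_fraction: float
    widespread_min_pools: int

    def class_of(self, key: str) -> str:
        for name in ("noninformative", "informative", "unique"):
            if key in getattr(self, name):
                return name
        raise KeyError(key)


def classify_haplotypes(
    pivot: PivotTable,
    widespread_fraction: float = 0.75,
    widespread_min_pools: int | None = None,
) -> HaplotypeClassification:
    """Classify query haplotypes by their spread across the panel.

    unique: present in no pool; noninformative: present in at least
    ``widespread_min_pools`` pools (default: 75% of the panel, the declared
    operationalization of "found at high frequency in nearly all present-day
    populations"); informative: the rest.
    """
    if not (0.0 < widespread_fraction <= 1.0):
        raise ValueError("widespread_fraction must be in (0, 1]")
    n_pools = pivot.counts.shape[1]
    threshold = (
        widespread_min_pools
        if widespread_min_pools is not None
        else math.ceil(widespread_fraction * n_pools)
    )
    if threshold < 1:
        raise ValueError("widespread_min_pools must be >= 1")
    presence = pivot.presence
    noninf, inf_, uniq = [], [], []
    for key in pivot.query_keys:
        n_present = int(presence.loc[key].sum()) if key in presence.index else 0
        if n_present == 0:
            uniq.append(key)
        elif n_present >= threshold:
            noninf.append(key)
        else:
            inf_.append(key)
    return HaplotypeClassification(
        noninformative=noninf, informative=inf_, unique=uniq,
        widespread_fraction=widespread_fraction, widespread_min_pools=threshold,
    )


def sharing_percentages(
    pivot: PivotTable, classification: HaplotypeClassification
) -> pd.DataFrame:
    """Per-pool percentage of members carrying a query-shared haplotype.

    Three columns: all shared matches, informative-only, noninformative-only
    (all = informative + noninformative since the classes are disjoint).
    """
    out = {}
    for label, keys in (
        ("informative", classification.informative),
        ("noninformative", classification.noninformative),
    ):
        keys = [k for k in keys if k in pivot.counts.index]
        hits = pivot.counts.loc[keys].sum(axis=0) if keys else 0.0
        out[label] = 100.0 * hits / pivot.pool_sizes
    frame = pd.DataFrame(out)
    frame["all"] = frame["informative"] + frame["noninformative"]
    return frame[["all", "informative", "noninformative"]]


def two_prop_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-tailed two-proportion z test with pooled variance.

    Returns (z, p) with p = 2 (1 - Phi(|z|)); degenerate cases (pooled
    proportion 0 or 1) give z = 0, p = 1.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    if var == 0.0:
        return 0.0, 1.0
    z = (p1 - p2) / math.sqrt(var)
    return z, 2.0 * (1.0 - norm.cdf(abs(z)))


def sharing_z_tests(
    pivot: PivotTable,
    classification: HaplotypeClassification,
    klass: str = "informative",
) -> pd.DataFrame:
    """Per-pool z test of the class sharing proportion against the pooled
    rest-of-panel proportion.  Raw two-tailed p values, no multiple-testing
    correction."""
    keys = [k for k in getattr(classification, klass) if k in pivot.counts.index]
    hits = pivot.counts.loc[keys].sum(axis=0) if keys else pd.Series(
        0, index=pivot.counts.columns
    )
    sizes = pivot.pool_sizes
    rows = []
    for pool in pivot.counts.columns:
        x1, n1 = int(hits[pool]), int(sizes[pool])
        x2 = int(hits.sum()) - x1
        n2 = int(sizes.sum()) - n1
        z, p = two_prop_z(x1, n1, x2, n2)
        rows.append({"pool": pool, "x": x1, "n": n1, "z": z, "p": p})
    return pd.DataFrame(rows).set_index("pool")


def bootstrap_sharing_ci(
    pool: PopulationSample,
    classification: HaplotypeClassification,
    reps: int = 100,
    seed: int = 0,
    level: float = 0.95,
    window: tuple[int, int] = TRIMMED_WINDOW,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap CI of the sharing percentage per class.

    Pool members are resampled with replacement; the classification (which
    query haplotypes count as informative/noninformative) stays fixed.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    keys = np.array(pool.canonical_keys(window))
    n = len(keys)
    flags = {
        "informative": np.isin(keys, classification.informative),
        "noninformative": np.isin(keys, classification.noninformative),
    }
    flags["all"] = flags["informative"] | flags["noninformative"]
    alpha = (1.0 - level) / 2.0
    out = {}
    idx = rng.integers(0, n, size=(reps, n))
    for label, flag in flags.items():
        pct = 100.0 * flag[idx].mean(axis=1)
        out[label] = (float(np.quantile(pct, alpha)),
                      float(np.quantile(pct, 1.0 - alpha)))
    return out
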