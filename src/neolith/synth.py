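"""Synthetic data generators with known ground truth.

The real modern comparative database behind the study (tens of thousands of
HVS-I records pooled into populations) is not redistributable, so every
pipeline input is emulated here: population pools with prescribed
haplogroup-category frequencies, star-like within-category haplotype
diversification around fixed founder haplotypes, planted query overlaps for
sharing analyses, and coalescent-simulated four-population panels with a
known generating model.  Every generator is seed-deterministic and returns
a bookkeeping ledger sufficient to recompute each downstream statistic by
direct counting.

Founder haplotypes occupy reserved positions disjoint across categories, so
category identity is recoverable from the haplotype itself; derived
mutations are placed only at positions no founder uses, which keeps the
assignment unambiguous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coalescent as coal
from .fixtures import paper_fixtures  # noqa: F401  (re-exported fixture access)
from .haplotypes import (
    CATEGORIES_19,
    TRIMMED_WINDOW,
    AFRICAN,
    EAST_EURASIAN,
    OTHER,
    Haplotype,
    Individual,
    PopulationSample,
    Variant,
)
from .sharing import PooledPanel

#: A representative haplogroup label per category (each bins back onto its
#: own category under the default scheme).
CATEGORY_LABELS: dict[str, str] = {
    "preHV": "preHV", "H": "H1", "HV": "HV", "J": "J1c", "T": "T2b",
    "I": "I", "N1a": "N1a1a", "K": "K1a", "V": "V", "W": "W", "X": "X2",
    "U2": "U2e", "U3": "U3a", "U4": "U4", "U5a": "U5a1", "U5b": "U5b1",
    AFRICAN: "L2a", EAST_EURASIAN: "D4", OTHER: "R9",
}

_FOUNDER_BLOCK_START = 16090
_FOUNDER_SPACING = 4
_DERIVED_START = (
    _FOUNDER_BLOCK_START + _FOUNDER_SPACING * len(CATEGORIES_19) + 4
)  # first position available for derived mutations


def _nonreference_allele(position: int, window: tuple[int, int],
                         preferred: str) -> str:
    """``preferred`` unless it coincides with the packaged synthetic
    reference base at that position (then the next base in ACGT order)."""
    from .haplotypes import synthetic_reference

    ref = synthetic_reference(window)
    base = ref[position - window[0]]
    if preferred != base:
        return preferred
    return next(b for b in "ACGT" if b != base)


def founder_haplotypes(
    window: tuple[int, int] = TRIMMED_WINDOW,
) -> dict[str, Haplotype]:
    """Fixed founder haplotype per category, at reserved disjoint positions.

    Category i carries two substitutions at positions 16090+4i and
    16091+4i (alleles always off-reference); the derived-mutation range
    starts above the founder block.
    """
    founders = {}
    for i, cat in enumerate(CATEGORIES_19):
        p = _FOUNDER_BLOCK_START + _FOUNDER_SPACING * i
        founders[cat] = Haplotype(
            frozenset({
                Variant(p, _nonreference_allele(p, window, "C")),
                Variant(p + 1, _nonreference_allele(p + 1, window, "T")),
            }),
            window=window,
        )
    return founders


@dataclass
class PoolRecipe:
    """Recipe for one synthetic population pool.

    ``freqs`` is a 19-category frequency vector (fractions summing to 1);
    ``derivation_rate`` is the Poisson mean number of extra private
    substitutions per lineage beyond its category founder (star-like
    diversification).
    """

    name: str
    n: int
    freqs: pd.Series
    derivation_rate: float = 0.8
    coordinates: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("pool size must be >= 1")
        if abs(float(self.freqs.sum()) - 1.0) > 1e-6:
            raise ValueError("frequencies must sum to 1")
        if (self.freqs < 0).any():
            raise ValueError("frequencies must be non-negative")


@dataclass
class PoolLedger:
    """Ground truth for one generated pool: per-member category and key."""

    categories: list[str]
    keys: list[str]

    @property
    def key_counts(self) -> Counter:
        return Counter(self.keys)

    @property
    def category_counts(self) -> Counter:
        return Counter(self.categories)


def generate_pool(
    recipe: PoolRecipe, window: tuple[int, int] = TRIMMED_WINDOW
) -> tuple[PopulationSample, PoolLedger]:
    """Draw a population pool from a recipe.

    Each member draws a category by frequency; its haplotype is the category
    founder plus Poisson(derivation_rate) private substitutions at unused
    positions.  Returns the sample and its ground-truth ledger.
    """
    from .haplotypes import synthetic_reference

    rng = np.random.default_rng(recipe.seed)
    founders = founder_haplotypes(window)
    ref = synthetic_reference(window)
    cats = list(recipe.freqs.index)
    draw = rng.choice(len(cats), size=recipe.n, p=recipe.freqs.to_numpy(dtype=float))
    derived_positions = np.arange(_DERIVED_START, window[1] + 1)
    individuals, categories, keys = [], [], []
    for i, ci in enumerate(draw):
        cat = cats[ci]
        variants = set(founders[cat].variants)
        n_extra = rng.poisson(recipe.derivation_rate)
        if n_extra > 0:
            extra = rng.choice(
                derived_positions, size=min(n_extra, len(derived_positions)),
                replace=False,
            )
            for pos in extra:
                allele = "G" if ref[int(pos) - window[0]] != "G" else "A"
                variants.add(Variant(int(pos), allele))
        hap = Haplotype(frozenset(variants), window=window)
        ind = Individual(
            id=f"{recipe.name}-{i:04d}",
            haplotype=hap,
            hg_mt=CATEGORY_LABELS[cat],
            age_generations=0.0,
        )
        individuals.append(ind)
        categories.append(cat)
        keys.append(hap.canonical_key())
    pop = PopulationSample(recipe.name, individuals, coordinates=recipe.coordinates)
    return pop, PoolLedger(categories=categories, keys=keys)


def recipe_from_frequencies(
    name: str,
    freqs_percent: pd.Series,
    n: int = 500,
    derivation_rate: float = 0.8,
    coordinates: tuple[float, float] | None = None,
    seed: int = 0,
) -> PoolRecipe:
    """Build a recipe from a published percent-frequency column."""
    f = freqs_percent.reindex(list(CATEGORIES_19)).fillna(0.0).astype(float)
    f = f / f.sum()
    return PoolRecipe(name=name, n=n, freqs=f, derivation_rate=derivation_rate,
                      coordinates=coordinates, seed=seed)


@dataclass
class PanelLedger:
    """Ground truth for a generated panel: per-pool key counts and plants."""

    pool_ledgers: dict[str, PoolLedger]
    planted: dict[str, Counter] = field(default_factory=dict)

    def key_count(self, pool: str, key: str) -> int:
        return self.pool_ledgers[pool].key_counts.get(key, 0)


def generate_panel(
    recipes: list[PoolRecipe],
    planted: dict[str, list[tuple[Haplotype, int]]] | None = None,
    window: tuple[int, int] = TRIMMED_WINDOW,
    seed: int = 0,
) -> tuple[PooledPanel, PanelLedger]:
    """Generate pools and plant specified query haplotypes at known counts.

    ``planted`` maps pool name -> [(haplotype, multiplicity), ...]; the
    planted haplotypes replace the haplotypes of that many members
    (deterministically, the first unplanted members), and the ledger records
    every plant.  Planting more copies than the pool holds is an error.
    """
    planted = planted or {}
    pools, pool_ledgers, plant_log = [], {}, {}
    for recipe in recipes:
        pop, ledger = generate_pool(recipe, window)
        plants = planted.get(recipe.name, [])
        total = sum(m for _, m in plants)
        if total > pop.size:
            raise ValueError(
                f"cannot plant {total} haplotypes into pool {recipe.name!r} "
                f"of size {pop.size}"
            )
        cursor = 0
        log = Counter()
        for hap, mult in plants:
            hap = hap.trim(window)
            key = hap.canonical_key()
            for _ in range(mult):
                ind = pop.individuals[cursor]
                ind.haplotype = hap
                ledger.keys[cursor] = key
                ledger.categories[cursor] = "planted"
                cursor += 1
            log[key] += mult
        pools.append(pop)
        pool_ledgers[recipe.name] = ledger
        plant_log[recipe.name] = log
    panel = PooledPanel(
        pools=pools, target_n=max(r.n for r in recipes), seed=seed,
        provenance={r.name: "synthetic" for r in recipes},
    )
    return panel, PanelLedger(pool_ledgers=pool_ledgers, planted=plant_log)


def coalescent_fixture(
    model_id: str,
    params: dict[str, float],
    seed: int = 0,
    sample_sizes: dict[str, int] | None = None,
) -> dict:
    """Four-population coded sequence panels from a built-in model.

    Returns the panels (group tag -> (n, L) uint8 array), the generating
    model id and true parameters; reproducible given the seed.
    """
    models = coal.builtin_models(sample_sizes=sample_sizes or coal.DESK_SAMPLES)
    if model_id not in models:
        raise ValueError(f"unknown model {model_id!r}")
    model = models[model_id]
    rng = np.random.default_rng(seed)
    genealogy = coal.simulate_genealogy(model, params, rng)
    seqs = coal.mutate(genealogy, model.mutation, rng)
    tags = np.array(genealogy.tip_tags)
    panels = {tag: seqs[tags == tag] for tag in ("HG", "LBK", "CE", "NE")}
    return {"model_id": model_id, "params": dict(params), "seed": seed,
            "panels": panels}
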