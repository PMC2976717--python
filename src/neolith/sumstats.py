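"""Within-sample diversity statistics and kinship deduplication.

Haplotype diversity h, segregating sites S, mean pairwise differences pi,
and Tajima's D over a common trimmed window, plus the within-graveyard
haplotype-sharing partition and the rule that drops putative kin duplicates
(keeping one representative per repeated haplotype).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

from .haplotypes import TRIMMED_WINDOW, PopulationSample


@dataclass
class DiversityReport:
    """Summary diversity statistics for one population sample."""

    name: str
    n: int
    k: int
    h: float
    S: int
    pi: float
    tajima_d: float | None

    def __post_init__(self) -> None:
        assert self.k <= self.n
        assert (self.k == 1) == (self.h == 0.0)
        assert self.S >= 0


def haplotype_diversity(
    pop: PopulationSample, window: tuple[int, int] = TRIMMED_WINDOW
) -> float:
    """Unbiased haplotype (gene) diversity h = n/(n-1) * (1 - sum p_i^2).

    p_i are the relative frequencies of the distinct haplotypes (by canonical
    key over the trimmed window).
    """
    keys = pop.canonical_keys(window)
    n = len(keys)
    if n < 2:
        raise ValueError("haplotype diversity needs n >= 2 haplotypes")
    counts = Counter(keys)
    sum_p2 = sum((c / n) ** 2 for c in counts.values())
    return n / (n - 1) * (1.0 - sum_p2)


def _pairwise_differences(h1, h2) -> int:
    """Substitution differences between two haplotypes on a shared window.

    A position carried by both with different alleles counts one difference
    (both differ from the reference, and from each other, at one site).
    """
    d = 0
    a = {v.position: v.allele for v in h1.variants}
    b = {v.position: v.allele for v in h2.variants}
    for pos in set(a) | set(b):
        if a.get(pos) != b.get(pos):
            d += 1
    return d


def site_statistics(
    pop: PopulationSample, window: tuple[int, int] = TRIMMED_WINDOW
) -> tuple[int, float]:
    """(segregating sites S, mean pairwise differences pi) over ``window``.

    A site is segregating if the sample carries more than one state there
    (the reference state counts when any member lacks a variant at a carried
    position); multi-allelic sites count once.
    """
    haps = [h.trim(window) for h in pop.haplotypes()]
    n = len(haps)
    if n < 2:
        raise ValueError("site statistics need n >= 2 haplotypes")
    states: dict[int, set[str]] = {}
    for h in haps:
        for v in h.variants:
            states.setdefault(v.position, set()).add(v.allele)
    S = 0
    for pos, alleles in states.items():
        carriers = sum(1 for h in haps if pos in h.positions)
        if len(alleles) > 1 or carriers < n:
            S += 1
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += _pairwise_differences(haps[i], haps[j])
    pi = total / (n * (n - 1) / 2)
    return S, pi


def tajimas_d(
    pop: PopulationSample, window: tuple[int, int] = TRIMMED_WINDOW
) -> float | None:
    """Tajima's D from S and pi with the standard normalizing constants.

    Returns ``None`` when S = 0 (statistic undefined).  Negative values
    indicate an excess of rare variants relative to the neutral
    constant-size expectation, e.g. after a population expansion.
    """
    n = len(pop.haplotypes())
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4 sequences")
    S, pi = site_statistics(pop, window)
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi - S / a1) / math.sqrt(var)


def diversity_report(
    pop: PopulationSample, window: tuple[int, int] = TRIMMED_WINDOW
) -> DiversityReport:
    keys = pop.canonical_keys(window)
    S, pi = site_statistics(pop, window)
    return DiversityReport(
        name=pop.name,
        n=len(keys),
        k=len(set(keys)),
        h=haplotype_diversity(pop, window),
        S=S,
        pi=pi,
        tajima_d=tajimas_d(pop, window) if len(keys) >= 4 else None,
    )


def within_sharing_partition(
    pop: PopulationSample, window: tuple[int, int] = TRIMMED_WINDOW
) -> dict[str, list[str]]:
    """Group distinct haplotype keys by within-sample multiplicity.

    Returns the keys observed once ("unique"), twice ("pairs"), three times
    ("triples") and more ("larger").
    """
    counts = Counter(pop.canonical_keys(window))
    out: dict[str, list[str]] = {"unique": [], "pairs": [], "triples": [], "larger": []}
    for key, c in sorted(counts.items()):
        if c == 1:
            out["unique"].append(key)
        elif c == 2:
            out["pairs"].append(key)
        elif c == 3:
            out["triples"].append(key)
        else:
            out["larger"].append(key)
    return out


def deduplicate_kin(
    pop: PopulationSample, window: tuple[int, int] = TRIMMED_WINDOW
) -> tuple[PopulationSample, int]:
    """Drop all but one member of each repeated-haplotype set.

    The retained representative is the lexicographically smallest id (the
    choice does not affect haplotype-level statistics).  Individuals without
    haplotypes are dropped as well (they cannot be screened).  Returns the
    reduced sample and the number of haplotype-bearing members removed.
    """
    bearers = [ind for ind in pop.individuals if ind.haplotype is not None]
    by_key: dict[str, list] = {}
    for ind in bearers:
        by_key.setdefault(ind.haplotype.trim(window).canonical_key(), []).append(ind)
    kept = [min(group, key=lambda ind: ind.id) for group in by_key.values()]
    kept.sort(key=lambda ind: ind.id)
    reduced = PopulationSample(
        f"{pop.name}-dedup", kept, pop.coordinates, pop.age_generations
    )
    return reduced, len(bearers) - len(kept)
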