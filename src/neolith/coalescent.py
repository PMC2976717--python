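"""Serial-coalescent simulator over demes with exponential growth, timed
demographic events, ancient (serially sampled) lineages, and finite-sites
mutation with gamma rate heterogeneity.

The simulator runs backwards in time.  Each deme ``d`` has a present-day
effective size ``Ne0`` (haploid female-lineage count; mtDNA is maternally
transmitted, so the pair-coalescence rate with k lineages in a deme of
current size N(t) is k(k-1)/(2 N(t))).  Forward-in-time exponential growth
at rate ``r`` means the backwards size trajectory is N(t) = Ne0 * exp(-r t);
inhomogeneous waiting times are drawn exactly with the usual time-rescaling
integral.  Demographic events are instantaneous: a *fusion* moves every
lineage of the source deme into the sink (backwards view of a population
split), a *pulse* moves each source lineage with the given probability
(backwards view of a one-generation migrant contribution), and a *resize*
re-anchors a deme's size and growth rate (used to hold an ancestral deme at
constant size).  Sampling groups enter the active lineage set at their
sampling age; groups and events scheduled at the same instant are processed
samples-first, so a sample taken "at" an admixture pulse participates in it.

The built-in model suite contrasts Neolithic-transition scenarios:

* ``H0a`` / ``H0b`` - one panmictic Eurasian deme, exponential growth from a
  5,000-female Palaeolithic deme starting 300 / 1,500 generations ago
  (population continuity).
* ``H1`` - separate Central European and Near Eastern demes fusing 1,500
  generations ago in a constant 5,000-female Upper Palaeolithic deme
  (cultural diffusion: farming spreads without gene flow).
* ``H2_25/50/75`` - as H1 plus a migration pulse from the Near Eastern into
  the Central European deme 290 generations ago, contributing 25/50/75% of
  the Central European deme (demic diffusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .distances import DistanceModelParams, fst_summary_vector

#: Generation time used to convert years to generations (25 y/generation).
GENERATION_YEARS = 25.0


class ModelValidationError(ValueError):
    """Raised when a model leaves sampled lineages with no way to coalesce."""


def derive_growth(Ne0: float, N_ancestral: float, duration: float) -> float:
    """Exponential rate reaching ``N_ancestral`` exactly at ``duration``.

    r = ln(Ne0 / N_ancestral) / duration, so the backwards trajectory
    N(t) = Ne0 exp(-r t) satisfies N(duration) = N_ancestral.
    """
    if Ne0 <= 0 or N_ancestral <= 0 or duration <= 0:
        raise ValueError("sizes and duration must be positive")
    return math.log(Ne0 / N_ancestral) / duration


@dataclass
class Deme:
    """One deme: present-day size and growth specification.

    ``Ne0`` may be a number or the name of a prior parameter.  ``growth`` is
    either a fixed rate or the tuple ``("derived", N_ancestral, duration)``
    meaning the rate is computed from the realized Ne0 via
    :func:`derive_growth` ("dependent growth rates").
    """

    id: str
    Ne0: float | str
    growth: float | tuple = 0.0


@dataclass
class DemographicEvent:
    """A timed event: fusion, migration pulse, or size/growth change."""

    time: float
    kind: str  # {"fusion", "pulse", "resize"}
    source: str | None = None
    sink: str | None = None
    proportion: float = 1.0
    new_size: float | None = None
    new_growth: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("fusion", "pulse", "resize"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.time < 0:
            raise ValueError("event times must be non-negative")
        if not (0.0 < self.proportion <= 1.0):
            raise ValueError("proportion must be in (0, 1]")


@dataclass
class SamplingGroup:
    """n lineages sampled from one deme at a given age (generations BP)."""

    tag: str
    deme: str
    n: int
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("sampling group size must be >= 1")


@dataclass
class MutationModel:
    """Finite-sites mutation: per-site gamma rate multipliers, ts:tv bias.

    ``mu`` is the per-site per-generation substitution rate; ``gamma_shape``
    the shape of the mean-1 gamma law of relative site rates (0.205 mimics
    mtDNA control-region heterogeneity); ``transition_bias`` the ratio of
    transition to transversion rates (mtDNA HVS-I is strongly
    transition-driven).
    """

    L: int = 377
    mu: float = 7.5e-6
    gamma_shape: float = 0.205
    transition_bias: float = 15.0

    def __post_init__(self) -> None:
        if min(self.L, self.mu, self.gamma_shape, self.transition_bias) <= 0:
            raise ValueError("all mutation parameters must be positive")


@dataclass
class ModelSpec:
    """A demographic scenario: demes, events, sampling groups, priors."""

    id: str
    demes: list[Deme]
    events: list[DemographicEvent]
    samples: list[SamplingGroup]
    mutation: MutationModel = field(default_factory=MutationModel)
    priors: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.time)
        deme_ids = {d.id for d in self.demes}
        for g in self.samples:
            if g.deme not in deme_ids:
                raise ModelValidationError(
                    f"sampling group {g.tag!r} references unknown deme {g.deme!r}"
                )
        for ev in self.events:
            for ref in (ev.source, ev.sink):
                if ref is not None and ref not in deme_ids:
                    raise ModelValidationError(
                        f"event at t={ev.time} references unknown deme {ref!r}"
                    )

    @property
    def k_free_parameters(self) -> int:
        return len(self.priors)

    def validate(self) -> None:
        """Check that all sampled lineages can eventually share one deme.

        Fusion events (and pulses with proportion 1, which are equivalent)
        must merge every deme holding samples into a single surviving deme;
        partial pulses are probabilistic and do not count.
        """
        alias = {d.id: d.id for d in self.demes}

        def find(x: str) -> str:
            while alias[x] != x:
                x = alias[x]
            return x

        survivors = {d.id for d in self.demes}
        for ev in self.events:
            if ev.kind == "fusion" or (ev.kind == "pulse" and ev.proportion >= 1.0):
                src, snk = find(ev.source), find(ev.sink)
                if src != snk:
                    alias[src] = snk
                    survivors.discard(src)
        sampled = {find(g.deme) for g in self.samples}
        if len(sampled) > 1:
            raise ModelValidationError(
                f"model {self.id!r}: sampled demes {sorted(sampled)} are never "
                "fused; lineages would be stranded"
            )

    def sample_priors(self, rng: np.random.Generator) -> dict[str, float]:
        return {
            name: float(rng.uniform(lo, hi)) for name, (lo, hi) in self.priors.items()
        }

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        out = asdict(self)
        out["priors"] = {k: list(v) for k, v in self.priors.items()}
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        return cls(
            id=data["id"],
            demes=[Deme(**d) if not isinstance(d.get("growth"), (list, tuple))
                   else Deme(d["id"], d["Ne0"], tuple(d["growth"]))
                   for d in data["demes"]],
            events=[DemographicEvent(**e) for e in data["events"]],
            samples=[SamplingGroup(**g) for g in data["samples"]],
            mutation=MutationModel(**data["mutation"]),
            priors={k: tuple(v) for k, v in data["priors"].items()},
        )

    def to_yaml(self, path) -> None:
        import yaml

        data = self.to_dict()
        for deme in data["demes"]:
            if isinstance(deme["growth"], tuple):
                deme["growth"] = list(deme["growth"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class Genealogy:
    """A rooted genealogy: tips 0..n-1, internal nodes appended in
    coalescence order; ``parent[root] == -1``; times in generations BP."""

    parent: np.ndarray
    node_time: np.ndarray
    n_tips: int
    tip_tags: list[str]

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    def total_branch_length(self) -> float:
        lengths = self.node_time[self.parent[:-1]] - self.node_time[:-1]
        return float(lengths.sum())


def _resolve_demes(
    model: ModelSpec, params: dict[str, float]
) -> dict[str, list[float]]:
    """Realize (N_ref, rate, t_ref) state per deme from sampled parameters."""
    state: dict[str, list[float]] = {}
    for deme in model.demes:
        ne0 = params[deme.Ne0] if isinstance(deme.Ne0, str) else float(deme.Ne0)
        if ne0 < 1:
            raise ValueError(f"deme {deme.id}: Ne0 must be >= 1")
        growth = deme.growth
        if isinstance(growth, tuple):
            kind, n_anc, duration = growth
            if kind != "derived":
                raise ValueError(f"unknown growth spec {growth!r}")
            rate = derive_growth(ne0, n_anc, duration)
        else:
            rate = float(growth)
        state[deme.id] = [ne0, rate, 0.0]
    return state


def simulate_genealogy(
    model: ModelSpec, params: dict[str, float], rng: np.random.Generator
) -> Genealogy:
    """Simulate one genealogy under the model with realized parameters."""
    model.validate()
    state = _resolve_demes(model, params)

    samples = sorted(model.samples, key=lambda g: g.time)
    tip_tags: list[str] = []
    tip_ids: list[list[int]] = []
    n_tips = 0
    for g in samples:
        ids = list(range(n_tips, n_tips + g.n))
        tip_ids.append(ids)
        tip_tags.extend([g.tag] * g.n)
        n_tips += g.n
    if n_tips < 2:
        raise ValueError("need >= 2 sampled lineages in total")

    total_nodes = 2 * n_tips - 1
    parent = np.full(total_nodes, -1, dtype=np.int64)
    node_time = np.zeros(total_nodes)
    for g, ids in zip(samples, tip_ids):
        node_time[ids] = g.time

    events = model.events  # already time-sorted
    lineages: dict[str, list[int]] = {d.id: [] for d in model.demes}
    t = 0.0
    si = ei = 0
    next_node = n_tips
    active = 0

    # buffered draws: scalar Generator calls dominate the event loop otherwise
    _exp_buf = rng.exponential(size=max(256, 4 * n_tips)).tolist()
    _uni_buf = rng.random(size=max(256, 4 * n_tips)).tolist()

    def exp_draw() -> float:
        if not _exp_buf:
            _exp_buf.extend(rng.exponential(size=1024).tolist())
        return _exp_buf.pop()

    def uni_draw() -> float:
        if not _uni_buf:
            _uni_buf.extend(rng.random(size=1024).tolist())
        return _uni_buf.pop()

    while True:
        next_s = samples[si].time if si < len(samples) else math.inf
        next_e = events[ei].time if ei < len(events) else math.inf
        t_break = min(next_s, next_e)

        # candidate coalescence: competing inhomogeneous risks across demes
        best_t = math.inf
        best_deme = None
        if active >= 2:
            for deme_id, nodes in lineages.items():
                k = len(nodes)
                if k < 2:
                    continue
                n_ref, rate, t_ref = state[deme_id]
                n_now = n_ref * math.exp(-rate * (t - t_ref))
                hazard = k * (k - 1) / (2.0 * n_now)
                e = exp_draw()
                if rate == 0.0:
                    w = e / hazard
                else:
                    arg = 1.0 + rate * e / hazard
                    w = math.log(arg) / rate if arg > 0 else math.inf
                if t + w < best_t:
                    best_t = t + w
                    best_deme = deme_id

        if best_t < t_break:
            t = best_t
            nodes = lineages[best_deme]
            k = len(nodes)
            i = int(uni_draw() * k)
            j = int(uni_draw() * (k - 1))
            if j >= i:
                j += 1
            a, b = nodes[i], nodes[j]
            parent[a] = parent[b] = next_node
            node_time[next_node] = t
            # replace the two children by the new node
            if i > j:
                i, j = j, i
            nodes[i] = next_node
            nodes.pop(j)
            next_node += 1
            active -= 1
            if active == 1 and si >= len(samples):
                break
            continue

        if t_break is math.inf or t_break == math.inf:
            raise ModelValidationError(
                f"model {model.id!r}: lineages stranded across demes with no "
                "remaining events"
            )
        t = t_break
        if next_s <= next_e:
            g = samples[si]
            lineages[g.deme].extend(tip_ids[si])
            active += len(tip_ids[si])
            si += 1
        else:
            ev = events[ei]
            ei += 1
            if ev.kind == "fusion":
                lineages[ev.sink].extend(lineages[ev.source])
                lineages[ev.source] = []
            elif ev.kind == "pulse":
                src = lineages[ev.source]
                stay, move = [], []
                for node in src:
                    (move if uni_draw() < ev.proportion else stay).append(node)
                lineages[ev.source] = stay
                lineages[ev.sink].extend(move)
            else:  # resize
                st = state[ev.source]
                n_now = st[0] * math.exp(-st[1] * (t - st[2]))
                st[0] = ev.new_size if ev.new_size is not None else n_now
                st[1] = ev.new_growth if ev.new_growth is not None else st[1]
                st[2] = t

    return Genealogy(parent=parent, node_time=node_time, n_tips=n_tips,
                     tip_tags=tip_tags)


def mutate(
    genealogy: Genealogy, model: MutationModel, rng: np.random.Generator
) -> np.ndarray:
    """Drop mutations on the genealogy; return coded tip sequences (n, L).

    Site rates are i.i.d. gamma(shape, mean 1) per site and per call;
    mutation counts are Poisson on branches; each mutation is a transition
    with probability bias/(bias+1) (the complementary base within the
    purine/pyrimidine class), otherwise a uniformly chosen transversion.
    The root state is the all-'A' sequence (arbitrary fixed anchor).
    """
    n_nodes = len(genealogy.parent)
    n_tips = genealogy.n_tips
    L = model.L
    lengths = (
        genealogy.node_time[genealogy.parent[: n_nodes - 1]]
        - genealogy.node_time[: n_nodes - 1]
    )
    total_len = float(lengths.sum())
    site_rates = rng.gamma(model.gamma_shape, 1.0 / model.gamma_shape, size=L)
    rate_sum = float(site_rates.sum())
    n_mut = rng.poisson(model.mu * rate_sum * total_len)

    if n_mut == 0:
        return np.zeros((n_tips, L), dtype=np.uint8)  # root = all 'A'

    # inverse-CDF draws (cheaper than Generator.choice for repeated calls)
    branch = np.searchsorted(
        np.cumsum(lengths), rng.random(n_mut) * total_len, side="right"
    ).clip(max=n_nodes - 2)
    site = np.searchsorted(
        np.cumsum(site_rates), rng.random(n_mut) * rate_sum, side="right"
    ).clip(max=L - 1)
    is_ts = rng.random(n_mut) < model.transition_bias / (model.transition_bias + 1)
    tv_pick = rng.integers(0, 2, size=n_mut).astype(np.uint8)

    order = np.argsort(branch, kind="stable")
    b_sorted = branch[order]
    s_sorted = site[order]
    ts_sorted = is_ts[order]
    tv_sorted = tv_pick[order]
    seg_starts = np.concatenate(
        [[0], np.flatnonzero(np.diff(b_sorted)) + 1, [n_mut]]
    )
    mutated = b_sorted[seg_starts[:-1]]
    segments: dict[int, tuple[int, int]] = {
        int(b): (int(seg_starts[i]), int(seg_starts[i + 1]))
        for i, b in enumerate(mutated)
    }

    # Distinct sequences are created only where a branch mutates; all other
    # nodes share their parent's row in the pool.
    pool = np.zeros((len(segments) + 1, L), dtype=np.uint8)
    seq_of = [0] * n_nodes  # node -> pool row; root = row 0
    parent = genealogy.parent.tolist()
    next_row = 1
    s_l = s_sorted.tolist()
    ts_l = ts_sorted.tolist()
    tv_l = tv_sorted.tolist()
    # walk from the root downwards (nodes were created in time order);
    # mutations on a branch apply in draw order (repeated hits overwrite)
    for node in range(n_nodes - 2, -1, -1):
        seg = segments.get(node)
        if seg is None:
            seq_of[node] = seq_of[parent[node]]
            continue
        lo, hi = seg
        pool[next_row] = pool[seq_of[parent[node]]]
        row = pool[next_row]
        for m in range(lo, hi):
            s = s_l[m]
            if ts_l[m]:
                row[s] = row[s] ^ 1  # other base, same class
            else:
                row[s] = tv_l[m] + (2 if row[s] < 2 else 0)
        seq_of[node] = next_row
        next_row += 1
    return pool[np.asarray(seq_of[:n_tips])]


def simulate_summary(
    model: ModelSpec,
    params: dict[str, float],
    rng: np.random.Generator | int,
    distance_params: DistanceModelParams | None = None,
) -> np.ndarray:
    """One genealogy + mutation simulation, summarized as the five pairwise
    F_ST values (HG-NE, HG-CE, LBK-NE, LBK-CE, LBK-HG)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if distance_params is None:
        # saturated pairs must stay finite inside AMOVA sums
        distance_params = DistanceModelParams(saturation="clip")
    genealogy = simulate_genealogy(model, params, rng)
    seqs = mutate(genealogy, model.mutation, rng)
    tags = np.array(genealogy.tip_tags)
    panels = {tag: seqs[tags == tag] for tag in ("HG", "LBK", "CE", "NE")}
    return fst_summary_vector(panels, distance_params)


# ---------------------------------------------------------------------------
# Built-in model suite
# ---------------------------------------------------------------------------

#: Published sampling design (lineage counts per group).
FULL_SAMPLES: dict[str, int] = {"CE": 1030, "NE": 737, "LBK": 42, "HG": 20}
#: Reduced sampling design for desk-scale simulation studies (same 290/320
#: generation sampling ages, roughly proportional sizes).
DESK_SAMPLES: dict[str, int] = {"CE": 40, "NE": 30, "LBK": 15, "HG": 8}

PALAEOLITHIC_SIZE = 5000.0
FUSION_TIME = 1500.0
MIGRATION_TIME = 290.0
#: Default hunter-gatherer sampling age (~8,000 y at 25 y per generation).
HG_AGE_DEFAULT = 320.0
LBK_AGE_DEFAULT = 290.0

MODEL_IDS = ("H0a", "H0b", "H1", "H2_25", "H2_50", "H2_75")


def builtin_models(
    sample_sizes: dict[str, int] | None = None,
    hg_age: float = HG_AGE_DEFAULT,
    lbk_age: float = LBK_AGE_DEFAULT,
    mutation: MutationModel | None = None,
) -> dict[str, ModelSpec]:
    """The six demographic scenarios, keyed by model id.

    Deme 0 is the Near Eastern deme, deme 1 the Central European deme (the
    single deme of H0a/H0b doubles as both).  Growth rates are derived from
    the sampled present-day sizes so that every deme reaches the 5,000-female
    Palaeolithic size exactly at its expansion start.
    """
    sizes = dict(sample_sizes or FULL_SAMPLES)
    mut = mutation or MutationModel()
    models: dict[str, ModelSpec] = {}

    def samples(ce_deme: str, ne_deme: str) -> list[SamplingGroup]:
        return [
            SamplingGroup("CE", ce_deme, sizes["CE"], 0.0),
            SamplingGroup("NE", ne_deme, sizes["NE"], 0.0),
            SamplingGroup("LBK", ce_deme, sizes["LBK"], lbk_age),
            SamplingGroup("HG", ce_deme, sizes["HG"], hg_age),
        ]

    for mid, duration in (("H0a", 300.0), ("H0b", 1500.0)):
        models[mid] = ModelSpec(
            id=mid,
            demes=[Deme("eurasia", "Ne0_eurasia",
                        ("derived", PALAEOLITHIC_SIZE, duration))],
            events=[DemographicEvent(duration, "resize", source="eurasia",
                                     new_size=PALAEOLITHIC_SIZE, new_growth=0.0)],
            samples=samples("eurasia", "eurasia"),
            mutation=mut,
            priors={"Ne0_eurasia": (1e5, 3e7)},
        )

    def two_deme(mid: str, extra_events: list[DemographicEvent]) -> ModelSpec:
        return ModelSpec(
            id=mid,
            demes=[
                Deme("NE0", "Ne0_NE", ("derived", PALAEOLITHIC_SIZE, FUSION_TIME)),
                Deme("CE1", "Ne0_CE", ("derived", PALAEOLITHIC_SIZE, FUSION_TIME)),
            ],
            events=sorted(
                extra_events
                + [
                    DemographicEvent(FUSION_TIME, "fusion", source="CE1", sink="NE0"),
                    DemographicEvent(FUSION_TIME, "resize", source="NE0",
                                     new_size=PALAEOLITHIC_SIZE, new_growth=0.0),
                ],
                key=lambda e: e.time,
            ),
            samples=samples("CE1", "NE0"),
            mutation=mut,
            priors={"Ne0_NE": (1e5, 1.2e7), "Ne0_CE": (1e5, 1.2e7)},
        )

    models["H1"] = two_deme("H1", [])
    for pct in (25, 50, 75):
        # forward-time: pct% of the CE deme derives from NE at the event;
        # backwards: each CE lineage moves to NE with that probability.
        models[f"H2_{pct}"] = two_deme(
            f"H2_{pct}",
            [DemographicEvent(MIGRATION_TIME, "pulse", source="CE1", sink="NE0",
                              proportion=pct / 100.0)],
        )
    return models
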