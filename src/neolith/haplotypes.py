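"""Data model and I/O for rCRS-relative mtDNA HVS-I haplotypes.

Haplotypes are stored as sets of single-base substitutions relative to the
revised Cambridge Reference Sequence (rCRS), anchored to 1-based nucleotide
positions (np).  The default analysis window is the hypervariable segment I,
np 15997-16409 inclusive; sequence-based statistics conventionally trim to
np 16069-16365 (297 sites) so that ancient and modern records span the same
alignment.  The compact literature notation drops the leading "16" thousands
("093C" means 16093C when the table header says "minus np 16000").

The module also provides haplogroup binning into the 19 frequency categories
used for ordination work (preHV, H, HV, J, T, I, N1a, K, V, W, X, U2, U3,
U4, U5a, U5b, a pooled African group, a pooled East-Eurasian group, and a
residual "other rare" group), and TSV/FASTA I/O for population samples.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Full HVS-I window (inclusive np range).
HVS1_WINDOW = (15997, 16409)
#: Trimmed window shared by ancient and modern records (inclusive).
TRIMMED_WINDOW = (16069, 16365)

BASES = ("A", "C", "G", "T")
#: Sentinels that denote an unusable / undetermined haplotype in input tables.
MISSING_SENTINELS = frozenset({"n.d.", "nd", "ambiguous", "?", "", "."})

_VARIANT_RE = re.compile(r"^(\d+)([ACGTacgt])$")
_INDEL_RE = re.compile(r"^\d+(\.\d+)?[-+]?(del|ins|d|i|[ACGTacgt]{2,})$", re.IGNORECASE)


class NotationError(ValueError):
    """Raised for malformed variant tokens."""


class RangeError(ValueError):
    """Raised when a parsed position falls outside the analysis window."""


@dataclass(frozen=True, order=True)
class Variant:
    """A single-base substitution at a 1-based rCRS position."""

    position: int
    allele: str

    def __post_init__(self) -> None:
        if self.allele not in BASES:
            raise NotationError(f"allele must be one of A/C/G/T, got {self.allele!r}")
        if self.position < 1:
            raise NotationError(f"position must be positive, got {self.position}")

    def __str__(self) -> str:  # pragma: no cover - trivial
        return f"{self.position}{self.allele}"


@dataclass(frozen=True)
class Haplotype:
    """A set of substitutions over an inclusive position window.

    The empty set is legal and denotes the reference motif (printed "rCRS"
    in the source tables).  At most one allele per position is allowed.
    """

    variants: frozenset[Variant]
    window: tuple[int, int] = HVS1_WINDOW

    def __post_init__(self) -> None:
        positions = [v.position for v in self.variants]
        if len(positions) != len(set(positions)):
            raise NotationError("duplicate position with conflicting alleles")

    @property
    def positions(self) -> set[int]:
        return {v.position for v in self.variants}

    def canonical_key(self) -> str:
        """Render as a sortable identity key, e.g. ``"16069T-16126C"``.

        Equal haplotypes map to equal keys; the empty set renders "rCRS".
        """
        if not self.variants:
            return "rCRS"
        return "-".join(str(v) for v in sorted(self.variants))

    def trim(self, window: tuple[int, int]) -> "Haplotype":
        """Restrict to variants inside the inclusive ``window``."""
        lo, hi = window
        kept = frozenset(v for v in self.variants if lo <= v.position <= hi)
        return Haplotype(kept, window=(lo, hi))

    def to_sequence(self, reference: str) -> str:
        """Materialize the haplotype against a reference over its window.

        ``reference`` must cover the window exactly (one base per position).
        """
        lo, hi = self.window
        if len(reference) != hi - lo + 1:
            raise ValueError(
                f"reference length {len(reference)} does not match window "
                f"[{lo},{hi}] ({hi - lo + 1} sites)"
            )
        seq = list(reference.upper())
        for v in self.variants:
            offset = v.position - lo
            if seq[offset] == v.allele:
                warnings.warn(
                    f"variant {v} equals the reference base (self-substitution)",
                    stacklevel=2,
                )
            seq[offset] = v.allele
        return "".join(seq)

    def __len__(self) -> int:
        return len(self.variants)


def parse_variant(token: str, offset_base: int = 16000) -> Variant:
    """Parse one variant token such as ``"093C"`` (with offset 16000).

    ``offset_base`` is added to the printed digits; tables that already print
    full positions use offset 0.  Insertion/deletion notation is rejected.
    """
    token = token.strip()
    if _INDEL_RE.match(token) and not _VARIANT_RE.match(token):
        raise NotationError(f"insertion/deletion token not supported: {token!r}")
    m = _VARIANT_RE.match(token)
    if not m:
        raise NotationError(f"malformed variant token: {token!r}")
    position = int(m.group(1)) + offset_base
    return Variant(position, m.group(2).upper())


def parse_haplotype(
    text: str,
    offset_base: int = 16000,
    window: tuple[int, int] = HVS1_WINDOW,
    strict: bool = False,
) -> Haplotype | None:
    """Parse a haplotype cell: ``"rCRS"``, a variant list, or a sentinel.

    Returns ``None`` for missing-data sentinels ("n.d.", "Ambiguous", ...),
    which is distinct from the empty (reference) haplotype.  In ``strict``
    mode, variants outside ``window`` raise :class:`RangeError`; otherwise
    they are kept (trimming is a separate, explicit step).
    """
    text = text.strip()
    if text.lower() in MISSING_SENTINELS or text.lower() == "ambiguous":
        return None
    if text.lower() == "rcrs":
        return Haplotype(frozenset(), window=window)
    tokens = [t for t in re.split(r"[,\s;/]+|(?<=[ACGTacgt])-", text) if t]
    variants: dict[int, Variant] = {}
    for tok in tokens:
        v = parse_variant(tok, offset_base=offset_base)
        if strict and not (window[0] <= v.position <= window[1]):
            raise RangeError(f"position {v.position} outside window {window}")
        prev = variants.get(v.position)
        if prev is not None and prev.allele != v.allele:
            raise NotationError(
                f"duplicate position {v.position} with conflicting alleles "
                f"{prev.allele}/{v.allele}"
            )
        variants[v.position] = v
    return Haplotype(frozenset(variants.values()), window=window)


@dataclass
class Individual:
    """One sampled person: identifier, haplotype and haplogroup labels."""

    id: str
    haplotype: Haplotype | None = None
    hg_mt: str | None = None
    hg_y: str | None = None
    age_generations: float | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def analyzable(self) -> bool:
        """Included in any analysis: needs a haplotype or an mtDNA haplogroup."""
        return self.haplotype is not None or self.hg_mt is not None


@dataclass
class PopulationSample:
    """A named collection of individuals, optionally geolocated and dated."""

    name: str
    individuals: list[Individual]
    coordinates: tuple[float, float] | None = None  # (lat, lon) decimal degrees
    age_generations: float = 0.0

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValueError(f"population {self.name!r} must contain >= 1 individual")

    @property
    def size(self) -> int:
        return len(self.individuals)

    def with_haplotypes(self) -> "PopulationSample":
        """Subset to individuals carrying a parseable haplotype."""
        kept = [ind for ind in self.individuals if ind.haplotype is not None]
        return PopulationSample(self.name, kept, self.coordinates, self.age_generations)

    def haplotypes(self, window: tuple[int, int] | None = None) -> list[Haplotype]:
        hs = [ind.haplotype for ind in self.individuals if ind.haplotype is not None]
        if window is not None:
            hs = [h.trim(window) for h in hs]
        return hs

    def canonical_keys(self, window: tuple[int, int] | None = None) -> list[str]:
        return [h.canonical_key() for h in self.haplotypes(window)]

    def sequences(
        self, reference: str, window: tuple[int, int] = TRIMMED_WINDOW
    ) -> list[str]:
        """Materialize trimmed sequences for all haplotype-bearing members."""
        return [h.trim(window).to_sequence(reference) for h in self.haplotypes(window)]


# ---------------------------------------------------------------------------
# Haplogroup binning
# ---------------------------------------------------------------------------

AFRICAN = "African (L, M1)"
EAST_EURASIAN = "East Eurasian (A, B, C, D, F, G, Z)"
OTHER = "Other rare hgs"

#: The 19 frequency categories, in the conventional reporting order.
CATEGORIES_19: tuple[str, ...] = (
    "preHV", "H", "HV", "J", "T", "I", "N1a", "K", "V", "W", "X",
    "U2", "U3", "U4", "U5a", "U5b", AFRICAN, EAST_EURASIAN, OTHER,
)


def _default_rules() -> dict[str, str]:
    rules: dict[str, str] = {
        "preHV": "preHV", "pre-HV": "preHV", "R0": "preHV",
        "N1a": "N1a",
        "U5a": "U5a", "U5b": "U5b",
        "U2": "U2", "U3": "U3", "U4": "U4",
        "HV": "HV",
        "H": "H", "J": "J", "T": "T", "I": "I", "K": "K",
        "V": "V", "W": "W", "X": "X",
        "L": AFRICAN, "M1": AFRICAN,
    }
    for hg in ("A", "B", "C", "D", "F", "G", "Z"):
        rules[hg] = EAST_EURASIAN
    return rules


@dataclass
class HaplogroupScheme:
    """Ordered longest-prefix mapping of haplogroup labels onto 19 categories."""

    categories: tuple[str, ...] = CATEGORIES_19
    rules: Mapping[str, str] = field(default_factory=_default_rules)
    residual: str = OTHER

    def bin(self, label: str) -> str:
        """Map a haplogroup label to its category by longest-prefix match."""
        if not label:
            raise ValueError("empty haplogroup label")
        label = label.strip()
        for length in range(len(label), 0, -1):
            cat = self.rules.get(label[:length])
            if cat is not None:
                return cat
        return self.residual


def bin_haplogroup(label: str, scheme: HaplogroupScheme | None = None) -> str:
    return (scheme or HaplogroupScheme()).bin(label)


def hg_frequency_vector(
    pop: PopulationSample,
    scheme: HaplogroupScheme | None = None,
    require_haplotype: bool = True,
) -> pd.Series:
    """Relative haplogroup-category frequencies for one population.

    By default only individuals with both an mtDNA haplogroup and a parseable
    haplotype are counted (coding-region-only specimens are excluded from
    sequence-comparable frequency work); pass ``require_haplotype=False`` to
    count every individual with a haplogroup label.
    """
    scheme = scheme or HaplogroupScheme()
    members = [
        ind
        for ind in pop.individuals
        if ind.hg_mt is not None and (ind.haplotype is not None or not require_haplotype)
    ]
    if not members:
        raise ValueError(f"population {pop.name!r} has no countable individuals")
    counts = pd.Series(0.0, index=list(scheme.categories))
    for ind in members:
        counts[scheme.bin(ind.hg_mt)] += 1.0
    freqs = counts / counts.sum()
    assert abs(freqs.sum() - 1.0) < 1e-9
    freqs.name = pop.name
    return freqs


def frequency_matrix(
    pops: Sequence[PopulationSample],
    scheme: HaplogroupScheme | None = None,
    require_haplotype: bool = True,
) -> pd.DataFrame:
    """Stack per-population frequency vectors into a populations x 19 table."""
    return pd.DataFrame(
        [hg_frequency_vector(p, scheme, require_haplotype) for p in pops]
    )


# ---------------------------------------------------------------------------
# Reference sequences
# ---------------------------------------------------------------------------

def synthetic_reference(window: tuple[int, int] = HVS1_WINDOW, seed: int = 413) -> str:
    """A deterministic synthetic reference segment spanning ``window``.

    Stands in for the real rCRS segment in tests and simulations; any fixed
    A/C/G/T string of the right length is a valid coordinate anchor because
    variants are defined positionally, not by reference identity.
    """
    rng = np.random.default_rng(seed)
    n = window[1] - window[0] + 1
    return "".join(rng.choice(list(BASES), size=n))


def load_reference_fasta(path) -> str:
    """Load a single-record FASTA and return its sequence upper-cased."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    return str(records[0].seq).upper()


def write_fasta(pop: PopulationSample, reference: str, path,
                window: tuple[int, int] = TRIMMED_WINDOW) -> None:
    """Export materialized sequences, one record per haplotype-bearing member."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = []
    for ind in pop.individuals:
        if ind.haplotype is None:
            continue
        seq = ind.haplotype.trim(window).to_sequence(reference)
        records.append(SeqRecord(Seq(seq), id=ind.id, description=""))
    seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Population TSV I/O
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["id", "population", "haplotype", "hg_mt", "hg_y",
                "age_generations", "lat", "lon"]


def load_population_table(
    path,
    offset_base: int = 0,
    window: tuple[int, int] = HVS1_WINDOW,
) -> list[PopulationSample]:
    """Load the standard population TSV (columns: id, population, haplotype,
    hg_mt, hg_y, age_generations, lat, lon; "." for missing; UTF-8).

    Haplotype cells hold canonical keys (full positions, offset 0) or
    offset notation if ``offset_base`` says so.  Malformed variant tokens are
    reported with their row number.  Unknown columns are ignored with a
    logged warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and df.columns.size == 0:
        logger.warning("empty population table: %s", path)
        return []
    missing = {"id", "population"} - set(df.columns)
    if missing:
        raise ValueError(f"population table lacks required columns: {sorted(missing)}")
    unknown = set(df.columns) - set(_TSV_COLUMNS)
    if unknown:
        logger.warning("ignoring unknown columns %s in %s", sorted(unknown), path)

    def cell(row, col):
        val = row.get(col, ".")
        return None if val in (".", "") else val

    pops: dict[str, dict] = {}
    for i, row in df.iterrows():
        hap_text = cell(row, "haplotype")
        try:
            hap = (
                parse_haplotype(hap_text, offset_base=offset_base, window=window)
                if hap_text is not None
                else None
            )
        except NotationError as exc:
            raise NotationError(f"row {i + 2} (id={row['id']!r}): {exc}") from exc
        meta = {}
        if hap_text is not None and hap is None:
            meta["haplotype_raw"] = hap_text
        age = cell(row, "age_generations")
        ind = Individual(
            id=row["id"],
            haplotype=hap,
            hg_mt=cell(row, "hg_mt"),
            hg_y=cell(row, "hg_y"),
            age_generations=float(age) if age is not None else None,
            metadata=meta,
        )
        entry = pops.setdefault(row["population"], {"inds": [], "coord": None})
        entry["inds"].append(ind)
        lat, lon = cell(row, "lat"), cell(row, "lon")
        if lat is not None and lon is not None:
            entry["coord"] = (float(lat), float(lon))

    if not pops:
        logger.warning("population table %s contains no rows", path)
        return []
    return [
        PopulationSample(name, e["inds"], coordinates=e["coord"])
        for name, e in pops.items()
    ]


def write_population_table(pops: Iterable[PopulationSample], path) -> None:
    """Write populations in the standard TSV dialect (round-trip stable)."""
    rows = []
    for pop in pops:
        lat, lon = pop.coordinates if pop.coordinates else (None, None)
        for ind in pop.individuals:
            hap = ind.haplotype.canonical_key() if ind.haplotype is not None else (
                ind.metadata.get("haplotype_raw", ".")
            )
            rows.append({
                "id": ind.id,
                "population": pop.name,
                "haplotype": hap,
                "hg_mt": ind.hg_mt if ind.hg_mt is not None else ".",
                "hg_y": ind.hg_y if ind.hg_y is not None else ".",
                "age_generations": ind.age_generations
                if ind.age_generations is not None else ".",
                "lat": lat if lat is not None else ".",
                "lon": lon if lon is not None else ".",
            })
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
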