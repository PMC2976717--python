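"""Sequence and frequency-based distances and ordination.

Implements the Kimura two-parameter (K2P) nucleotide distance with
gamma-distributed rate heterogeneity across sites, the distance-based AMOVA
estimator of pairwise F_ST between population samples, Nei's standard
genetic distance on haplogroup-frequency vectors, and classical PCA / metric
MDS ordination of frequency tables.

Sequences are encoded A=0, G=1, C=2, T=3 so that purine/pyrimidine class is
``code >= 2`` and transitions are within-class differences; this lets the
pairwise transition/transversion counts for a whole panel be computed with a
handful of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import TRIMMED_WINDOW, PopulationSample

_CODE = {"A": 0, "G": 1, "C": 2, "T": 3}
_SATURATION_FLOOR_SITES = 0.5  # pseudo-count floor, in sites, for log arguments


@dataclass(frozen=True)
class DistanceModelParams:
    """Nucleotide distance model: K2P with optional gamma rate variation.

    ``gamma_shape`` is the shape of the (mean-1) gamma law of relative site
    rates; 0.205 is the conventional value for the human mtDNA control
    region.  ``model`` selects plain K2P, K2P+gamma, or the uncorrected
    p-distance.  ``saturation`` controls what happens when the K2P logarithm
    arguments hit zero: "nan" marks the distance undefined, "clip" floors the
    arguments at half a site (keeps AMOVA components finite), "raise" errors.
    """

    gamma_shape: float = 0.205
    model: str = "K2P+gamma"  # {"K2P", "K2P+gamma", "p-distance"}
    saturation: str = "nan"  # {"nan", "clip", "raise"}

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.model not in ("K2P", "K2P+gamma", "p-distance"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.saturation not in ("nan", "clip", "raise"):
            raise ValueError(f"unknown saturation policy {self.saturation!r}")


def encode_sequences(seqs: list[str] | np.ndarray) -> np.ndarray:
    """Encode sequences as an (n, L) uint8 array (A=0,G=1,C=2,T=3)."""
    if isinstance(seqs, np.ndarray) and seqs.dtype == np.uint8:
        return seqs
    table = np.full(128, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        table[ord(base)] = code
        table[ord(base.lower())] = code
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    coded = table[arr].reshape(len(seqs), -1)
    if (coded == 255).any():
        raise ValueError("sequences contain non-ACGT characters")
    return coded


_B0 = np.array([1.0, 1.0, -1.0, -1.0], dtype=np.float32)  # +1 purine
_B1 = np.array([1.0, -1.0, 1.0, -1.0], dtype=np.float32)  # +- within class


def ts_tv_counts(coded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise transition and transversion counts for an encoded panel.

    Each state is mapped to a pair of +-1 coordinates (purine/pyrimidine
    class, and parity within class); three Gram matrices then recover the
    same-class and identical-state counts:

        same_class = (S + B0) / 2,  same_state = (S + B0 + B1 + C) / 4

    with B0 = b0 b0^T, B1 = b1 b1^T, C = (b0*b1)(b0*b1)^T over the S
    variable columns.  Invariant columns contribute nothing to either count.
    """
    n, L = coded.shape
    variable = (coded != coded[0]).any(axis=0)
    sub = coded[:, variable]
    s = sub.shape[1]
    if s == 0:
        z = np.zeros((n, n))
        return z, z.copy()
    b0 = _B0[sub]
    b1 = _B1[sub]
    g0 = b0 @ b0.T
    g1 = b1 @ b1.T
    gc = (b0 * b1) @ (b0 * b1).T
    same = (s + g0 + g1 + gc) / 4.0
    tv = (s - g0) / 2.0  # class differs => transversion
    ts = (s - same) - tv  # differs but same class => transition
    return np.rint(ts).astype(float), np.rint(tv).astype(float)


def _k2p_from_pq(P: np.ndarray, Q: np.ndarray, params: DistanceModelParams):
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if params.model == "p-distance":
        return P + Q
    saturated = (w1 <= 0) | (w2 <= 0)
    if np.any(saturated):
        if params.saturation == "raise":
            raise FloatingPointError("saturated sequence pair (K2P undefined)")
        w1 = np.maximum(w1, np.finfo(float).tiny)
        w2 = np.maximum(w2, np.finfo(float).tiny)
    with np.errstate(over="ignore", divide="ignore"):
        if params.model == "K2P":
            d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        else:
            a = params.gamma_shape
            d = (a / 2.0) * (w1 ** (-1.0 / a) - 1.0) + (a / 4.0) * (
                w2 ** (-1.0 / a) - 1.0
            )
    if np.any(saturated) and params.saturation == "nan":
        d = np.where(saturated, np.nan, d)
    return d


def k2p_distance_matrix(
    seqs: list[str] | np.ndarray, params: DistanceModelParams | None = None
) -> np.ndarray:
    """Pairwise K2P(+gamma) distance matrix for a sequence panel.

    Transition/transversion counts are integers, so the (usually few)
    distinct count pairs are transformed through a lookup table rather than
    evaluating the power functions on every matrix cell.
    """
    params = params or DistanceModelParams()
    coded = encode_sequences(seqs)
    L = coded.shape[1]
    ts, tv = ts_tv_counts(coded)
    tsi = ts.astype(np.intp)
    tvi = tv.astype(np.intp)
    ts_grid = np.arange(tsi.max() + 1, dtype=float)
    tv_grid = np.arange(tvi.max() + 1, dtype=float)
    TS, TV = np.meshgrid(ts_grid, tv_grid, indexing="ij")
    if params.saturation == "clip":
        # floor the log arguments by nudging counts half a site off saturation
        floor = _SATURATION_FLOOR_SITES
        TV = np.minimum(TV, (L - floor) / 2.0)
        TS = np.minimum(TS, (L - floor - TV) / 2.0)
    table = _k2p_from_pq(TS / L, TV / L, params)
    d = table[tsi, tvi]
    np.fill_diagonal(d, 0.0)
    return d


def k2p_gamma_distance(
    seqA: str, seqB: str, params: DistanceModelParams | None = None
) -> float:
    """K2P(+gamma) distance between two equal-length A/C/G/T sequences.

    Returns NaN (the undefined marker) for saturated pairs under the default
    policy.
    """
    if len(seqA) != len(seqB):
        raise ValueError("sequences must have equal length")
    return float(k2p_distance_matrix([seqA, seqB], params)[0, 1])


# ---------------------------------------------------------------------------
# AMOVA-based pairwise F_ST
# ---------------------------------------------------------------------------

def amova_fst_from_distances(d: np.ndarray, n1: int) -> float:
    """Two-population F_ST from a pooled pairwise-distance matrix.

    The first ``n1`` rows are population A, the rest population B.  The
    distances serve as squared deviations in the AMOVA sums of squares;
    variance components follow the standard two-level decomposition:

        SSD_T = (1/N) sum_{i<j} d_ij
        SSD_W = sum_p (1/n_p) sum_{i<j in p} d_ij
        sigma2_w = SSD_W / (N - 2)
        sigma2_a = (SSD_T - SSD_W - sigma2_w) / n',  n' = N - (n1^2+n2^2)/N

        F_ST = sigma2_a / (sigma2_a + sigma2_w)

    Negative estimates are reported as computed (no clipping).
    """
    N = d.shape[0]
    n2 = N - n1
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 sequences")
    # diagonal is zero, so the upper-triangle sum is half the full sum
    ssd_t = d.sum() / (2.0 * N)
    ssd_w = (
        d[:n1, :n1].sum() / (2.0 * n1) + d[n1:, n1:].sum() / (2.0 * n2)
    )
    ssd_a = ssd_t - ssd_w
    sigma_w = ssd_w / (N - 2)
    n_prime = N - (n1 * n1 + n2 * n2) / N
    sigma_a = (ssd_a - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return float(sigma_a / denom)


def pairwise_fst_from_sequences(
    seqsA: list[str] | np.ndarray,
    seqsB: list[str] | np.ndarray,
    params: DistanceModelParams | None = None,
) -> float:
    codedA = encode_sequences(seqsA)
    codedB = encode_sequences(seqsB)
    pooled = np.vstack([codedA, codedB])
    d = k2p_distance_matrix(pooled, params)
    if np.isnan(d).any():
        raise FloatingPointError(
            "saturated pairs produced undefined distances; use the 'clip' "
            "saturation policy for F_ST on highly diverged panels"
        )
    return amova_fst_from_distances(d, codedA.shape[0])


def pairwise_fst(
    popA: PopulationSample,
    popB: PopulationSample,
    reference: str,
    params: DistanceModelParams | None = None,
    window: tuple[int, int] = TRIMMED_WINDOW,
) -> float:
    """AMOVA F_ST between two population samples over a trimmed window."""
    seqsA = popA.sequences(reference, window)
    seqsB = popB.sequences(reference, window)
    if len(seqsA) < 2 or len(seqsB) < 2:
        raise ValueError("each population needs >= 2 sequences")
    return pairwise_fst_from_sequences(seqsA, seqsB, params)


#: Ordering of the five-statistic summary vector: each ancient sample against
#: the modern pools, plus the ancient-ancient contrast.
SUMMARY_PAIRS: tuple[tuple[str, str], ...] = (
    ("HG", "NE"),
    ("HG", "CE"),
    ("LBK", "NE"),
    ("LBK", "CE"),
    ("LBK", "HG"),
)


def fst_summary_vector(
    panels: dict[str, list[str] | np.ndarray],
    params: DistanceModelParams | None = None,
) -> np.ndarray:
    """Five pairwise F_ST values (HG-NE, HG-CE, LBK-NE, LBK-CE, LBK-HG).

    ``panels`` maps the four group tags HG/LBK/CE/NE to sequence panels.
    The pooled pairwise distance matrix is computed once and each pairwise
    F_ST is assembled from its blocks (identical to calling
    :func:`pairwise_fst_from_sequences` per pair).
    """
    missing = {"HG", "LBK", "CE", "NE"} - set(panels)
    if missing:
        raise ValueError(f"missing panels: {sorted(missing)}")
    order = ("HG", "LBK", "CE", "NE")
    coded = {tag: encode_sequences(panels[tag]) for tag in order}
    pooled = np.vstack([coded[tag] for tag in order])
    d = k2p_distance_matrix(pooled, params)
    if np.isnan(d).any():
        raise FloatingPointError(
            "saturated pairs produced undefined distances; use the 'clip' "
            "saturation policy for F_ST on highly diverged panels"
        )
    offsets = {}
    start = 0
    for tag in order:
        offsets[tag] = slice(start, start + coded[tag].shape[0])
        start += coded[tag].shape[0]
    block = {
        (a, b): float(d[offsets[a], offsets[b]].sum())
        for i, a in enumerate(order)
        for b in order[i:]
    }
    out = []
    for a, b in SUMMARY_PAIRS:
        saa = block[(a, a)]
        sbb = block[(b, b)]
        sab = block[(a, b)] if (a, b) in block else block[(b, a)]
        n1 = offsets[a].stop - offsets[a].start
        n2 = offsets[b].stop - offsets[b].start
        out.append(_amova_fst_from_block_sums(saa, sab, sbb, n1, n2))
    return np.array(out)


def _amova_fst_from_block_sums(
    saa: float, sab: float, sbb: float, n1: int, n2: int
) -> float:
    """AMOVA F_ST from full (ordered-pair) block sums of the distance matrix;
    algebraically identical to :func:`amova_fst_from_distances`."""
    N = n1 + n2
    ssd_t = (saa / 2.0 + sbb / 2.0 + sab) / N
    ssd_w = saa / (2.0 * n1) + sbb / (2.0 * n2)
    sigma_w = ssd_w / (N - 2)
    n_prime = N - (n1 * n1 + n2 * n2) / N
    sigma_a = ((ssd_t - ssd_w) - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return float(sigma_a / denom)


# ---------------------------------------------------------------------------
# Frequency-based distance and ordination
# ---------------------------------------------------------------------------

def nei_distance(freqA: np.ndarray, freqB: np.ndarray) -> float:
    """Nei's standard genetic distance D = -ln I on frequency vectors.

    I is the normalized identity sum(x*y)/sqrt(sum(x^2)*sum(y^2)).  Returns
    ``inf`` when the vectors share no categories (I = 0).
    """
    x = np.asarray(freqA, dtype=float)
    y = np.asarray(freqB, dtype=float)
    if x.shape != y.shape:
        raise ValueError("frequency vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("frequencies must be non-negative")
    identity = x @ y / np.sqrt((x @ x) * (y @ y))
    if identity <= 0:
        return float("inf")
    return float(-np.log(min(identity, 1.0)))


def nei_distance_matrix(freqs: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Nei-distance matrix over the rows of a frequency table."""
    names = list(freqs.index)
    X = freqs.to_numpy(dtype=float)
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = nei_distance(X[i], X[j])
    return pd.DataFrame(out, index=names, columns=names)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # populations x components
    loadings: pd.DataFrame  # components x categories
    explained_fraction: np.ndarray


def pca_on_frequencies(
    freqs: pd.DataFrame, n_components: int | None = None, standardize: bool = False
) -> PcaResult:
    """Classical PCA of a populations x categories frequency table.

    Columns are centered (and optionally standardized for a
    correlation-matrix PCA); loadings are exported for biplot overlays.
    """
    from sklearn.decomposition import PCA

    if freqs.shape[0] < 3:
        raise ValueError("PCA needs >= 3 populations")
    X = freqs.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant column -> zero loading
        X = X / sd
    k = n_components or min(X.shape)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    comp_names = [f"PC{i + 1}" for i in range(pca.n_components_)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=freqs.index, columns=comp_names),
        loadings=pd.DataFrame(pca.components_, index=comp_names,
                              columns=freqs.columns),
        explained_fraction=pca.explained_variance_ratio_,
    )


@dataclass
class MdsResult:
    coordinates: pd.DataFrame
    stress: float  # raw SMACOF stress (sum of squared residuals / 2)
    stress1: float  # Kruskal stress-1


def classical_scaling(d: np.ndarray, dims: int = 2) -> np.ndarray:
    """Torgerson classical scaling, used as the deterministic MDS start."""
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def mds_from_distances(
    d: np.ndarray | pd.DataFrame, dims: int = 2, seed: int = 0
) -> MdsResult:
    """Metric least-squares MDS of a symmetric zero-diagonal distance matrix.

    Uses SMACOF initialized from classical scaling, so the embedding is
    deterministic given the seed.  Infinite entries must be capped upstream.
    """
    from sklearn.manifold import MDS

    names = list(d.index) if isinstance(d, pd.DataFrame) else None
    mat = np.asarray(d, dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(mat, mat.T) or not np.allclose(np.diag(mat), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    init = classical_scaling(mat, dims)
    try:  # current scikit-learn parameter names
        mds = MDS(
            n_components=dims,
            metric="precomputed",
            metric_mds=True,
            n_init=1,
            init="classical_mds",
            random_state=seed,
            normalized_stress=False,
        )
        coords = mds.fit_transform(mat, init=init)
    except (TypeError, ValueError):  # older releases
        mds = MDS(
            n_components=dims,
            dissimilarity="precomputed",
            metric=True,
            n_init=1,
            random_state=seed,
            normalized_stress=False,
        )
        coords = mds.fit_transform(mat, init=init)
    iu = np.triu_indices(mat.shape[0], k=1)
    fitted = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    denom = (mat[iu] ** 2).sum()
    stress1 = float(np.sqrt(((fitted[iu] - mat[iu]) ** 2).sum() / denom)) if denom else 0.0
    frame = pd.DataFrame(coords, index=names, columns=[f"dim{i+1}" for i in range(dims)])
    return MdsResult(coordinates=frame, stress=float(mds.stress_), stress1=stress1)
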