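"""Embedded published data: the Derenburg graveyard haplotype table, pooled
haplogroup frequency columns, the observed pairwise F_ST matrix, and the
published AIC values for the six demographic models.

These small tables are the study's printed inputs and regression anchors;
everything larger (the modern comparative database) is emulated by
:mod:`neolith.synth`.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .haplotypes import (
    HVS1_WINDOW,
    Individual,
    PopulationSample,
    parse_haplotype,
)

# ---------------------------------------------------------------------------
# Derenburg graveyard: 26 sampled individuals, 22 with HVS-I haplotypes.
# Haplotype strings are in "minus np 16000" notation; "rCRS" = reference
# motif; "n.d." / "Ambiguous" = no usable sequence.  hg_mt is the HVS-I-based
# haplogroup; hg_coding the coding-region SNP assay result; hg_y the
# Y-chromosome haplogroup where typed.
# ---------------------------------------------------------------------------

_DERENBURG_ROWS: list[tuple[str, str, str | None, str | None, str | None]] = [
    # (id, haplotype, hg_mt, hg_coding, hg_y)
    ("deb09", "rCRS", "H", "H", None),
    ("deb06", "Ambiguous", None, "H", None),
    ("deb11", "n.d.", None, "T", None),
    ("deb10", "093C, 224C, 311C", "K", "K", None),
    ("deb23", "093C, 223T, 292T", "W", "W", None),
    ("deb12I", "298C", "V", "V", None),
    ("deb03", "147A, 172C, 223T, 248T, 320T, 355T", "N1a", None, None),
    ("deb15", "126C, 294T, 296T, 304C", "T2", "T", None),
    ("deb05", "311C", "HV", "HV", None),
    ("deb22", "092C, 129A, 147A, 154C, 172C, 223T, 248T, 320T, 355T",
     "N1a", "N1", None),
    ("deb20", "311C", "HV", "HV", "F*(xG,H,I,J,K)"),
    ("deb21", "rCRS", "H", "H", None),
    ("deb01", "147A, 172C, 223T, 248T, 355T", "N1a", "N1", None),
    ("deb04", "311C", "HV", "HV", None),
    ("deb26", "069T, 126C", "J", "J", None),
    ("deb32", "n.d.", None, "T", None),
    ("deb30", "069T, 126C", "J", "J", None),
    ("deb29II", "n.d.", None, "K", None),
    ("deb34II", "093C, 223T, 292T", "W", "W", "G2a3"),
    ("deb33", "126C, 147T, 293G, 294T, 296T, 297C, 304C", "T2", "T", None),
    ("deb02", "224C, 311C", "K", "K", None),
    ("deb36", "093C, 256T, 270T, 399G", "U5a1a", "U", None),
    ("deb38", "093C, 224C, 311C", "K", "K", "F*(xG,H,I,J,K)"),
    ("deb35II", "126C, 189C, 294T, 296T", "T", "T", None),
    ("deb37I", "069T, 126C", "J", "J", None),
    ("deb39", "126C, 294T, 296T, 304C", "T2", "T", None),
]

#: Sampling age of the Derenburg LBK graveyard in generations before present
#: (~7,250 y at 25 y per generation).
LBK_AGE_GENERATIONS = 290.0


def derenburg_table1() -> PopulationSample:
    """The Derenburg graveyard sample (26 individuals, 22 with haplotypes)."""
    individuals = []
    for sid, hap_text, hg_mt, hg_coding, hg_y in _DERENBURG_ROWS:
        hap = parse_haplotype(hap_text, offset_base=16000, window=HVS1_WINDOW)
        meta = {}
        if hap is None:
            meta["haplotype_raw"] = hap_text
        if hg_coding is not None:
            meta["hg_coding"] = hg_coding
        individuals.append(
            Individual(
                id=sid,
                haplotype=hap,
                hg_mt=hg_mt,
                hg_y=hg_y,
                age_generations=LBK_AGE_GENERATIONS,
                metadata=meta,
            )
        )
    return PopulationSample(
        "DEB22", individuals, coordinates=(51.87, 10.91),
        age_generations=LBK_AGE_GENERATIONS,
    )


# ---------------------------------------------------------------------------
# Pooled haplogroup frequency columns (percentages over the 19 categories).
# Order follows the published frequency block; "Asian hgs" is the pooled
# East-Eurasian group.
# ---------------------------------------------------------------------------

_FREQ_INDEX = [
    "East Eurasian (A, B, C, D, F, G, Z)",
    "African (L, M1)",
    "preHV", "H", "HV", "J", "T", "I", "N1a", "K", "V", "W", "X",
    "U2", "U3", "U4", "U5a", "U5b",
    "Other rare hgs",
]

_FREQ_COLUMNS: dict[str, list[float]] = {
    "European": [1.62, 0.65, 0.37, 43.35, 1.40, 8.49, 9.26, 2.23, 0.30,
                 5.39, 4.35, 2.03, 1.22, 1.04, 1.26, 4.04, 5.46, 3.89, 3.67],
    "NearEast": [2.09, 6.43, 3.26, 23.74, 5.80, 10.59, 8.91, 1.97, 0.32,
                 6.67, 0.77, 2.25, 2.52, 1.52, 4.43, 2.10, 2.53, 0.64, 13.45],
    "DEB22": [0.00, 0.00, 0.00, 13.64, 13.64, 13.64, 13.64, 0.00, 13.64,
              13.64, 4.55, 9.09, 0.00, 0.00, 0.00, 0.00, 4.55, 0.00, 0.00],
    "LBK20": [0.00, 0.00, 0.00, 25.00, 0.00, 5.00, 25.00, 0.00, 15.00,
              15.00, 5.00, 5.00, 0.00, 0.00, 5.00, 0.00, 0.00, 0.00, 0.00],
    "LBK42": [0.00, 0.00, 0.00, 19.05, 7.14, 9.52, 19.05, 0.00, 14.29,
              14.29, 4.76, 7.14, 0.00, 0.00, 2.38, 0.00, 2.38, 0.00, 0.00],
    "LBK34": [0.00, 0.00, 0.00, 17.65, 2.94, 5.88, 23.53, 0.00, 17.65,
              14.71, 5.88, 5.88, 0.00, 0.00, 2.94, 0.00, 2.94, 0.00, 0.00],
    "HunterGatherers": [0.00, 0.00, 0.00, 0.00, 0.00, 4.76, 9.52, 0.00, 0.00,
                        4.76, 0.00, 0.00, 0.00, 0.00, 0.00, 9.52, 23.80,
                        28.57, 19.05],
}


def table2_frequencies(as_fraction: bool = False) -> pd.DataFrame:
    """Published pooled haplogroup frequency columns (percent by default)."""
    df = pd.DataFrame(_FREQ_COLUMNS, index=_FREQ_INDEX)
    return df / 100.0 if as_fraction else df


# ---------------------------------------------------------------------------
# Observed pairwise F_ST between the two ancient samples and the two modern
# pools, as used for the coalescent goodness-of-fit work.
# ---------------------------------------------------------------------------

_FST_ORDER = ["HunterGatherers", "NearEast", "LBK", "CentralEurope"]
_FST_LOWER = {
    ("NearEast", "HunterGatherers"): 0.04192,
    ("LBK", "HunterGatherers"): 0.09298,
    ("LBK", "NearEast"): 0.03019,
    ("CentralEurope", "HunterGatherers"): 0.03445,
    ("CentralEurope", "NearEast"): 0.00939,
    ("CentralEurope", "LBK"): 0.03958,
}

#: Ordering of the five-statistic summary vector used for model comparison.
SUMMARY_ORDER: tuple[tuple[str, str], ...] = (
    ("HunterGatherers", "NearEast"),
    ("HunterGatherers", "CentralEurope"),
    ("LBK", "NearEast"),
    ("LBK", "CentralEurope"),
    ("LBK", "HunterGatherers"),
)


def table3_fst() -> pd.DataFrame:
    """Observed symmetric pairwise F_ST matrix (diagonal 0)."""
    mat = pd.DataFrame(0.0, index=_FST_ORDER, columns=_FST_ORDER)
    for (a, b), value in _FST_LOWER.items():
        mat.loc[a, b] = value
        mat.loc[b, a] = value
    return mat


def observed_summary_vector() -> np.ndarray:
    """The five observed F_ST values in summary order
    (HG-NE, HG-CE, LBK-NE, LBK-CE, LBK-HG)."""
    mat = table3_fst()
    return np.array([mat.loc[a, b] for a, b in SUMMARY_ORDER])


# ---------------------------------------------------------------------------
# Published model-comparison table: AIC per demographic model.
# ---------------------------------------------------------------------------

MODEL_IDS = ("H0a", "H0b", "H1", "H2_25", "H2_50", "H2_75")


def table4_aic() -> pd.Series:
    """Published AIC values for the six demographic models."""
    return pd.Series(
        [97.78, 120.37, 89.19, 82.56, 78.52, 78.07], index=list(MODEL_IDS),
        name="AIC",
    )


def table4_weights() -> pd.Series:
    """Published Akaike weights for the six demographic models."""
    return pd.Series(
        [2.76164e-5, 3.42478e-10, 0.002018032, 0.055596369, 0.418527622,
         0.52383036],
        index=list(MODEL_IDS),
        name="akaike_weight",
    )


def paper_fixtures() -> dict:
    """All embedded published tables as typed values, with a checksum."""
    fixtures = {
        "derenburg_table1": derenburg_table1(),
        "table2_frequencies": table2_frequencies(),
        "table3_fst": table3_fst(),
        "table4_aic": table4_aic(),
    }
    digest = hashlib.sha256()
    digest.update(repr(_DERENBURG_ROWS).encode())
    digest.update(repr(_FREQ_COLUMNS).encode())
    digest.update(repr(sorted(_FST_LOWER.items())).encode())
    digest.update(table4_aic().to_json().encode())
    fixtures["checksum"] = digest.hexdigest()
    return fixtures
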