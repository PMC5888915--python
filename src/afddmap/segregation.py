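"""Zygosity classes, genotype groups G1-G5, and F1 segregation-type models.

In an F1 cross of two heterogeneously heterozygous parents (a pseudo-testcross
design), a biallelic DNA variant can follow one of six segregation types in
JoinMap-style notation: <ab×cd>, <ef×eg>, <hk×hk>, <lm×ll>, <lm×mm>, <nn×np>
and the monomorphic <qq×qq>.  The first-listed allele of the seed parent is
taken to be in coupling with the dominant causal allele; three configurations
are informative for mapping a dominant trait:

* type I  <lm×mm>  — variant heterozygous only in the seed parent; expected
  pooled variant-allele frequency at full linkage: 50% (mutant pool) / 0%
  (wildtype pool); such variants are mutant-pool-specific.
* type II <lm×ll>  — pollen parent homozygous for the variant: 100% / 50%.
* type III <hk×hk> — both parents heterozygous: 75% / 25%.

All three give a directional allele-frequency difference (AFDD, mutant −
wildtype) of 50 percentage points at full linkage.

Pool-level zygosity of a call is classified from its allele frequency:
15-80% (inclusive) heterozygous, >80% homozygous, <15% low-frequency.  The
zygosity pair of a pool-common variant defines the genotype groups
G1 (het/het), G2 (hom/het), G3 (het/hom), G4 (hom/hom) and G5 ("complex",
three or more distinct bases at the site).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .variant_io import BiPoolVariant, Membership

__all__ = [
    "Zygosity",
    "ZygosityBands",
    "classify_zygosity",
    "SegregationTypeModel",
    "SEGREGATION_TYPES",
    "expected_pool_frequency",
    "assign_genotype_group",
    "group_common_variants",
    "infer_candidate_types",
    "evaluate_type_response",
    "TypeResponseSummary",
]


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"
    LOW_FREQUENCY = "low_frequency"


@dataclass(frozen=True)
class ZygosityBands:
    """Frequency bands (percent) defining pool-level zygosity calls."""

    het_min: float = 15.0
    het_max: float = 80.0

    def __post_init__(self) -> None:
        if not 0.0 < self.het_min < self.het_max < 100.0:
            raise ValueError("need 0 < het_min < het_max < 100")


def classify_zygosity(frequency: float, bands: ZygosityBands | None = None) -> Zygosity:
    """Classify a pool allele frequency: [15, 80] het, (80, 100] hom, [0, 15) low."""
    bands = bands or ZygosityBands()
    if not 0.0 <= frequency <= 100.0:
        raise ValueError(f"frequency {frequency} outside [0, 100]")
    if frequency < bands.het_min:
        return Zygosity.LOW_FREQUENCY
    if frequency <= bands.het_max:
        return Zygosity.HETEROZYGOUS
    return Zygosity.HOMOZYGOUS


@dataclass(frozen=True)
class SegregationTypeModel:
    """One F1 segregation type with its parental allele configuration.

    ``seed_genotype``'s first allele is the one in coupling with the dominant
    causal allele in the seed (mutant) parent; ``variant_allele`` is the
    allele tracked as the variant relative to the reference genome.
    """

    name: str
    seed_genotype: tuple[str, str]
    pollen_genotype: tuple[str, str]
    variant_allele: str
    informative: bool
    type_label: str | None = None  # "I", "II", "III" for the informative trio

    @property
    def expected_freq_mutant_pool(self) -> float:
        return expected_pool_frequency(self, 0.0, "mutant")

    @property
    def expected_freq_wildtype_pool(self) -> float:
        return expected_pool_frequency(self, 0.0, "wildtype")


def _model(name, seed, pollen, variant, informative, label=None):
    return SegregationTypeModel(name, seed, pollen, variant, informative, label)


#: The six base segregation types (plus both phases being covered by the
#: coupling convention).  Keys use the JoinMap-style "×"; ASCII "x" aliases
#: are accepted by :func:`get_type`.
SEGREGATION_TYPES: Mapping[str, SegregationTypeModel] = {
    m.name: m
    for m in [
        _model("<lm×mm>", ("l", "m"), ("m", "m"), "l", True, "I"),
        _model("<lm×ll>", ("l", "m"), ("l", "l"), "l", True, "II"),
        _model("<hk×hk>", ("h", "k"), ("h", "k"), "h", True, "III"),
        _model("<nn×np>", ("n", "n"), ("n", "p"), "p", False),
        _model("<qq×qq>", ("q", "q"), ("q", "q"), "q", False),
        _model("<ab×cd>", ("a", "b"), ("c", "d"), "a", False),
        _model("<ef×eg>", ("e", "f"), ("e", "g"), "e", False),
    ]
}


def get_type(name: str) -> SegregationTypeModel:
    """Look up a segregation type by name; accepts '×' or ASCII 'x'."""
    if name in SEGREGATION_TYPES:
        return SEGREGATION_TYPES[name]
    alias = name.replace("x", "×")
    if alias in SEGREGATION_TYPES:
        return SEGREGATION_TYPES[alias]
    raise KeyError(f"unknown segregation type {name!r}")


def expected_pool_frequency(
    seg_type: SegregationTypeModel | str,
    linkage_r: float,
    pool: str,
) -> float:
    """Mendelian expectation (percent) of the tracked variant allele in a pool.

    Computed by exact enumeration of the seed parent's four ordered gamete
    classes — (causal, coupling allele) with weight (1-r)/2 each and the two
    recombinant classes with weight r/2 — conditioned on the progeny
    phenotype (causal allele carried or not, the trait being dominant), plus
    the pollen parent's unconditioned transmission.  At r=0 this reproduces
    the textbook values (type I 50/0, type II 100/50, type III 75/25); at
    r=0.5 both pools equal the unlinked expectation.
    """
    if isinstance(seg_type, str):
        seg_type = get_type(seg_type)
    if not 0.0 <= linkage_r <= 0.5:
        raise ValueError(f"recombination fraction {linkage_r} outside [0, 0.5]")
    if pool not in ("mutant", "wildtype"):
        raise ValueError(f"pool must be 'mutant' or 'wildtype', got {pool!r}")
    r = linkage_r
    a1, a2 = seg_type.seed_genotype
    v = seg_type.variant_allele
    # seed gametes: (carries_causal, allele) with weights; condition on phenotype
    gametes = [
        (True, a1, (1 - r) / 2), (True, a2, r / 2),
        (False, a1, r / 2), (False, a2, (1 - r) / 2),
    ]
    want_causal = pool == "mutant"
    total_w = sum(w for carries, _, w in gametes if carries == want_causal)
    p_seed = sum(w for carries, allele, w in gametes
                 if carries == want_causal and allele == v) / total_w
    p_pollen = seg_type.pollen_genotype.count(v) / 2.0
    return 100.0 * (p_seed + p_pollen) / 2.0


# ---------------------------------------------------------------------------
# Genotype groups
# ---------------------------------------------------------------------------

_GROUP_MATRIX = {
    (Zygosity.HETEROZYGOUS, Zygosity.HETEROZYGOUS): "G1",
    (Zygosity.HOMOZYGOUS, Zygosity.HETEROZYGOUS): "G2",
    (Zygosity.HETEROZYGOUS, Zygosity.HOMOZYGOUS): "G3",
    (Zygosity.HOMOZYGOUS, Zygosity.HOMOZYGOUS): "G4",
}

GROUP_LABELS = ["G1", "G2", "G3", "G4", "G5", "excluded"]


def assign_genotype_group(
    variant: BiPoolVariant,
    site_allele_count: int,
    bands: ZygosityBands | None = None,
) -> str:
    """Genotype group of a pool-common variant.

    ``site_allele_count`` is the number of distinct DNA bases observed at the
    site across both pools including the reference; >= 3 distinct bases (two
    or more variant alleles) makes the site "complex" (G5).  A call below the
    heterozygous band in either pool is excluded from grouping and reported
    separately as ``"excluded"``.
    """
    bands = bands or ZygosityBands()
    if variant.membership is not Membership.COMMON:
        raise ValueError("genotype groups are defined for pool-common variants")
    if site_allele_count >= 3:
        return "G5"
    zm = classify_zygosity(variant.mutant_call.frequency, bands)
    zw = classify_zygosity(variant.wildtype_call.frequency, bands)
    if Zygosity.LOW_FREQUENCY in (zm, zw):
        return "excluded"
    return _GROUP_MATRIX[(zm, zw)]


def site_allele_counts(variants: Iterable[BiPoolVariant]) -> dict[tuple[str, int], int]:
    """Distinct base count per site (reference + distinct alt alleles)."""
    alts: dict[tuple[str, int], set[str]] = {}
    for v in variants:
        site = (v.key.chromosome, v.key.position)
        alts.setdefault(site, set()).add(v.key.alt_allele)
    return {site: 1 + len(a) for site, a in alts.items()}


def group_common_variants(
    common: Iterable[BiPoolVariant],
    bands: ZygosityBands | None = None,
    site_counts: Mapping[tuple[str, int], int] | None = None,
) -> tuple[dict[str, list[BiPoolVariant]], pd.DataFrame]:
    """Partition common variants into G1-G5 / excluded.

    Returns the per-group variant lists and a count/percentage summary table.
    ``site_counts`` may carry allele counts computed over the *full* joined
    variant set (so pool-specific alleles at the same site count toward
    complexity); by default counts are computed from ``common`` itself.
    """
    common = list(common)
    counts = dict(site_counts) if site_counts is not None \
        else site_allele_counts(common)
    groups: dict[str, list[BiPoolVariant]] = {g: [] for g in GROUP_LABELS}
    for v in common:
        g = assign_genotype_group(
            v, counts.get((v.key.chromosome, v.key.position), 2), bands)
        groups[g].append(v)
    total = len(common)
    summary = pd.DataFrame(
        {
            "group": GROUP_LABELS,
            "count": [len(groups[g]) for g in GROUP_LABELS],
        }
    )
    summary["percent"] = 100.0 * summary["count"] / total if total else 0.0
    return groups, summary


#: Which segregation types can produce each genotype group.  Reconstructed
#: from the expected pool frequencies of each type in both phases; only the
#: three starred configurations are informative for a dominant trait.
CANDIDATE_TYPES: Mapping[str, tuple[str, ...]] = {
    "G1": ("<hk×hk>", "<nn×np>"),
    "G2": ("<lm×ll>",),
    "G3": ("<lm×mm>",),
    "G4": ("<qq×qq>",),
    "G5": ("<ab×cd>", "<ef×eg>"),
}


def infer_candidate_types(group: str | BiPoolVariant,
                          bands: ZygosityBands | None = None,
                          site_allele_count: int = 2) -> set[SegregationTypeModel]:
    """Segregation types consistent with a genotype group (or a variant)."""
    if isinstance(group, BiPoolVariant):
        group = assign_genotype_group(group, site_allele_count, bands)
    names = CANDIDATE_TYPES.get(group, ())
    return {SEGREGATION_TYPES[n] for n in names}


# ---------------------------------------------------------------------------
# Frequency-band response evaluation
# ---------------------------------------------------------------------------

@dataclass
class TypeResponseSummary:
    """Wildtype-pool frequency distribution of a mutant-pool frequency band.

    Selecting common variants that are near-homozygous in the mutant pool
    (>= 95%) should concentrate the wildtype-pool frequencies near 50% where
    type II variants are enriched; selecting the 70-80% band should
    concentrate them near 25% (type III), in the causal region.
    """

    mutant_band: tuple[float, float]
    n_selected: int
    per_chromosome: pd.Series
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray

    @property
    def mode_frequency(self) -> float | None:
        """Center of the most populated 5-point wildtype-frequency bin."""
        if self.n_selected == 0:
            return None
        i = int(np.argmax(self.histogram_counts))
        return float((self.histogram_edges[i] + self.histogram_edges[i + 1]) / 2)


def evaluate_type_response(
    common: Iterable[BiPoolVariant],
    mutant_band: tuple[float, float],
    bin_width: float = 5.0,
) -> TypeResponseSummary:
    """Select common variants by mutant-pool frequency band and summarize the
    wildtype-pool frequency distribution (histogram bin width 5 points).
    """
    lo, hi = mutant_band
    if not (0.0 <= lo <= hi <= 100.0):
        raise ValueError(f"band {mutant_band} outside [0, 100]")
    selected = [v for v in common
                if v.membership is Membership.COMMON
                and lo <= v.mutant_call.frequency <= hi]
    wt_freqs = np.array([v.wildtype_call.frequency for v in selected])
    chroms = pd.Series([v.key.chromosome for v in selected], dtype=str)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(wt_freqs, bins=edges) if len(selected) else (
        np.zeros(len(edges) - 1, dtype=int), edges)
    return TypeResponseSummary(
        mutant_band=(lo, hi),
        n_selected=len(selected),
        per_chromosome=chroms.value_counts().sort_index(),
        histogram_counts=counts,
        histogram_edges=edges,
    )
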