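"""F1 cross-and-pooling simulator: the test harness for the mapping method.

Simulates a cross of two heterogeneously heterozygous parents segregating a
dominant causal allele, phenotype-based pooling of the progeny, and pooled
short-read sampling of every variant site.  Variants of each segregation
type are placed uniformly along the genome; each is assigned a random phase
(whether its tracked variant allele is in coupling with the causal allele in
the seed parent) and transmitted to progeny with a crossover between the
variant and the causal locus at the Haldane recombination fraction
``r = (1 - exp(-2 d / 100)) / 2`` for map distance ``d = cM_per_Mb * Mb``.
Variants on other chromosomes segregate independently (r = 0.5).

Per variant and pool, the pooled variant-allele fraction q is the realized
allele count over ``2 * pool size``; sequencing draws coverage ~
Poisson(depth_mean) (min 1) and variant reads ~ Binomial(coverage, q).
Calls with zero variant reads are suppressed, as a real caller would, which
is what makes variants pool-specific versus common downstream.

All randomness flows from the single configured seed through one named
generator; identical configurations give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .variant_io import (
    GenomeLayout,
    PoolCall,
    VariantClass,
    VariantKey,
    write_pool_table,
    write_pool_vcf,
)

__all__ = [
    "CrossConfig",
    "simulate_cross",
    "write_sim",
    "haldane_r",
    "default_layout",
    "apple_like_layout",
    "DEFAULT_TYPE_DENSITIES",
]

BASES = np.array(list("ACGT"))

#: Variants per Mb for each segregation type.  Chosen to emulate a real
#: pooled-sequencing variant load: ~330 pool-common variants per Mb in total,
#: with type II ~3% of common variants and the monomorphic <qq×qq> class
#: (homozygous non-reference in both parents) ~9%.
DEFAULT_TYPE_DENSITIES: Mapping[str, float] = {
    "<lm×mm>": 40.0,
    "<lm×ll>": 10.0,
    "<hk×hk>": 60.0,
    "<nn×np>": 190.0,
    "<qq×qq>": 30.0,
}

# seed/pollen zygosity for the tracked variant allele, per segregation type
_TYPE_PARENTS: Mapping[str, tuple[str, str]] = {
    "<lm×mm>": ("het", "hom_ref"),
    "<lm×ll>": ("het", "hom_var"),
    "<hk×hk>": ("het", "het"),
    "<nn×np>": ("hom_ref", "het"),
    "<qq×qq>": ("hom_var", "hom_var"),
}


def default_layout() -> GenomeLayout:
    """Compact five-chromosome test genome (5 × 30 Mb)."""
    return GenomeLayout([(f"chr{i}", 30_000_000) for i in range(1, 6)])


def apple_like_layout() -> GenomeLayout:
    """Seventeen-chromosome preset at ~31 Mb each (~526 Mb assembled genome)."""
    return GenomeLayout([(f"chr{i}", 31_000_000) for i in range(1, 18)])


def haldane_r(distance_cM: float) -> float:
    """Haldane map function: recombination fraction from map distance in cM."""
    return float((1.0 - np.exp(-2.0 * distance_cM / 100.0)) / 2.0)


@dataclass
class CrossConfig:
    """Full specification of a simulated F1 cross, pooling and sequencing."""

    layout: GenomeLayout = field(default_factory=default_layout)
    causal_chromosome: str = "chr3"
    causal_position: int = 15_500_000
    n_mutant_pool: int = 17
    n_wildtype_pool: int = 16
    type_densities: dict = field(
        default_factory=lambda: dict(DEFAULT_TYPE_DENSITIES))
    cM_per_Mb: float = 2.0
    depth_mean: float = 25.0
    misclassification_rate: float = 0.0
    #: probability a variant's tracked allele is in coupling with the causal
    #: allele in the seed parent (0.5 = random phase)
    phase_linked_prob: float = 0.5
    #: mean of the Poisson start-diversity model for unique read starts
    start_diversity_mean: float = 8.0
    #: optional second causal locus modulating penetrance (expressivity);
    #: penetrance multipliers apply to causal-allele carriers only
    second_causal_chromosome: str | None = None
    penetrance_with_w2: float = 1.0
    penetrance_without_w2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_mutant_pool, self.n_wildtype_pool) <= 0:
            raise ValueError("pool sizes must be positive")
        if any(d < 0 for d in self.type_densities.values()):
            raise ValueError("type densities must be >= 0")
        if not 0.0 <= self.misclassification_rate < 0.5:
            raise ValueError("misclassification_rate must be in [0, 0.5)")
        if self.causal_chromosome not in self.layout:
            raise ValueError(
                f"causal chromosome {self.causal_chromosome!r} absent from layout")
        unknown = set(self.type_densities) - set(_TYPE_PARENTS)
        if unknown:
            raise ValueError(f"unknown segregation types: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CrossConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "layout" in raw:
            raw["layout"] = GenomeLayout(
                [(str(n), int(l)) for n, l in raw["layout"]])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layout"] = [[n, l] for n, l in self.layout.chromosomes]
        return d


def _draw_progeny(config: CrossConfig, rng: np.random.Generator):
    """Draw progeny until both pools are full; returns causal-carrier flags.

    Phenotype is 'mutant' iff the progeny carries the dominant causal allele,
    modulated by penetrance (optional second locus) and flipped at the
    misclassification rate.
    """
    mut: list[bool] = []
    wt: list[bool] = []
    use_w2 = config.second_causal_chromosome is not None or \
        config.penetrance_with_w2 != 1.0 or config.penetrance_without_w2 != 1.0
    while len(mut) < config.n_mutant_pool or len(wt) < config.n_wildtype_pool:
        has_w = bool(rng.random() < 0.5)
        if has_w:
            if use_w2:
                has_w2 = bool(rng.random() < 0.5)
                pen = (config.penetrance_with_w2 if has_w2
                       else config.penetrance_without_w2)
            else:
                pen = 1.0
            pheno_mutant = bool(rng.random() < pen)
        else:
            pheno_mutant = False
        if rng.random() < config.misclassification_rate:
            pheno_mutant = not pheno_mutant
        if pheno_mutant and len(mut) < config.n_mutant_pool:
            mut.append(has_w)
        elif not pheno_mutant and len(wt) < config.n_wildtype_pool:
            wt.append(has_w)
    return np.array(mut, dtype=bool), np.array(wt, dtype=bool)


def _seed_dosage(
    rng: np.random.Generator,
    state: str,
    n_carrier: int,
    n_noncarrier: int,
    p_carrier: np.ndarray,
    p_noncarrier: np.ndarray,
) -> np.ndarray:
    """Pooled variant-allele count transmitted by the seed parent."""
    n = len(p_carrier)
    total = n_carrier + n_noncarrier
    if state == "hom_var":
        return np.full(n, total, dtype=np.int64)
    if state == "hom_ref":
        return np.zeros(n, dtype=np.int64)
    return (rng.binomial(n_carrier, p_carrier)
            + rng.binomial(n_noncarrier, p_noncarrier))


def _pollen_dosage(rng: np.random.Generator, state: str, n_pool: int,
                   n_variants: int) -> np.ndarray:
    if state == "hom_var":
        return np.full(n_variants, n_pool, dtype=np.int64)
    if state == "hom_ref":
        return np.zeros(n_variants, dtype=np.int64)
    return rng.binomial(n_pool, 0.5, size=n_variants)


def simulate_cross(
    config: CrossConfig,
) -> tuple[list[PoolCall], list[PoolCall], pd.DataFrame]:
    """Run one simulated cross; returns (mutant calls, wildtype calls, truth).

    The truth table records, per emitted variant site, the segregation type,
    phase, recombination fraction to the causal locus, and the realized pool
    allele fractions (percent) before read sampling — including sites whose
    call was suppressed in one pool by zero sampled variant reads.
    """
    rng = np.random.default_rng(config.seed)
    gw_mut, gw_wt = _draw_progeny(config, rng)
    n_car_m, n_non_m = int(gw_mut.sum()), int((~gw_mut).sum())
    n_car_w, n_non_w = int(gw_wt.sum()), int((~gw_wt).sum())

    mutant_calls: list[PoolCall] = []
    wildtype_calls: list[PoolCall] = []
    truth_rows: list[pd.DataFrame] = []

    type_names = [t for t in _TYPE_PARENTS if config.type_densities.get(t, 0) > 0]

    for chrom, length in config.layout.chromosomes:
        mb = length / 1e6
        n_per_type = {t: int(round(config.type_densities[t] * mb))
                      for t in type_names}
        n_total = sum(n_per_type.values())
        if n_total == 0:
            continue
        positions = np.sort(
            rng.choice(length, size=n_total, replace=False).astype(np.int64) + 1)
        # interleave types uniformly by random assignment of positions
        labels = np.repeat(
            np.arange(len(type_names)),
            [n_per_type[t] for t in type_names],
        )
        rng.shuffle(labels)
        ref_idx = rng.integers(0, 4, size=n_total)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n_total)) % 4
        refs = BASES[ref_idx]
        alts = BASES[alt_idx]
        if chrom == config.causal_chromosome:
            d_cm = config.cM_per_Mb * np.abs(
                positions - config.causal_position) / 1e6
            r = (1.0 - np.exp(-2.0 * d_cm / 100.0)) / 2.0
        else:
            r = np.full(n_total, 0.5)
        phase = rng.random(n_total) < config.phase_linked_prob

        for ti, tname in enumerate(type_names):
            mask = labels == ti
            n_t = int(mask.sum())
            if n_t == 0:
                continue
            seed_state, pollen_state = _TYPE_PARENTS[tname]
            r_t = r[mask]
            phase_t = phase[mask]
            p_car = np.where(phase_t, 1.0 - r_t, r_t)
            p_non = np.where(phase_t, r_t, 1.0 - r_t)

            q = {}
            for pool, n_car, n_non, n_pool in (
                ("mutant", n_car_m, n_non_m, config.n_mutant_pool),
                ("wildtype", n_car_w, n_non_w, config.n_wildtype_pool),
            ):
                dosage = (
                    _seed_dosage(rng, seed_state, n_car, n_non, p_car, p_non)
                    + _pollen_dosage(rng, pollen_state, n_pool, n_t)
                )
                q[pool] = dosage / (2.0 * n_pool)

            calls_by_pool = {}
            for pool, n_pool, out in (
                ("mutant", config.n_mutant_pool, mutant_calls),
                ("wildtype", config.n_wildtype_pool, wildtype_calls),
            ):
                cov = np.maximum(rng.poisson(config.depth_mean, size=n_t), 1)
                vr = rng.binomial(cov, q[pool])
                fwd = rng.binomial(vr, 0.5)
                usp = np.minimum(
                    vr,
                    np.maximum(rng.poisson(config.start_diversity_mean,
                                           size=n_t), 1),
                )
                calls_by_pool[pool] = (cov, vr, fwd, usp)
                pos_t = positions[mask]
                refs_t = refs[mask]
                alts_t = alts[mask]
                for j in np.flatnonzero(vr > 0):
                    out.append(PoolCall(
                        key=VariantKey(chrom, int(pos_t[j]), VariantClass.SNV,
                                       str(refs_t[j]), str(alts_t[j])),
                        pool_label=pool,
                        variant_reads=int(vr[j]),
                        coverage=int(cov[j]),
                        frequency=100.0 * float(vr[j]) / float(cov[j]),
                        forward_reads=int(fwd[j]),
                        reverse_reads=int(vr[j] - fwd[j]),
                        unique_start_positions=int(usp[j]),
                    ))
            truth_rows.append(pd.DataFrame({
                "chromosome": chrom,
                "position": positions[mask],
                "reference": refs[mask],
                "allele": alts[mask],
                "seg_type": tname,
                "phase_linked": phase_t,
                "r": r_t,
                "q_mutant": 100.0 * q["mutant"],
                "q_wildtype": 100.0 * q["wildtype"],
            }))

    key = lambda c: (c.key.chromosome, c.key.position, c.key.alt_allele)
    mutant_calls.sort(key=key)
    wildtype_calls.sort(key=key)
    if truth_rows:
        truth = pd.concat(truth_rows, ignore_index=True)
        truth = truth.sort_values(["chromosome", "position"]).reset_index(drop=True)
    else:
        truth = pd.DataFrame(columns=[
            "chromosome", "position", "reference", "allele", "seg_type",
            "phase_linked", "r", "q_mutant", "q_wildtype"])
    return mutant_calls, wildtype_calls, truth


def write_sim(
    mutant_calls: list[PoolCall],
    wildtype_calls: list[PoolCall],
    truth: pd.DataFrame,
    out_dir: str | Path,
    config: CrossConfig | None = None,
) -> dict[str, Path]:
    """Write simulator output: pool TSVs, minimal VCFs, truth table, config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout = config.layout if config is not None else _layout_from_calls(
        mutant_calls + wildtype_calls)
    paths = {
        "mutant_table": out / "mutant.tsv",
        "wildtype_table": out / "wildtype.tsv",
        "mutant_vcf": out / "mutant.vcf",
        "wildtype_vcf": out / "wildtype.vcf",
        "truth": out / "truth.tsv",
    }
    params = f"seed={config.seed}" if config is not None else ""
    write_pool_table(mutant_calls, paths["mutant_table"], parameters=params)
    write_pool_table(wildtype_calls, paths["wildtype_table"], parameters=params)
    write_pool_vcf(mutant_calls, paths["mutant_vcf"], layout, "mutant")
    write_pool_vcf(wildtype_calls, paths["wildtype_vcf"], layout, "wildtype")
    truth.to_csv(paths["truth"], sep="\t", index=False)
    if config is not None:
        cfg_path = out / "sim_config.yaml"
        cfg_path.write_text(yaml.safe_dump(config.to_dict()))
        paths["config"] = cfg_path
    return paths


def _layout_from_calls(calls: list[PoolCall]) -> GenomeLayout:
    maxima: dict[str, int] = {}
    for c in calls:
        maxima[c.key.chromosome] = max(
            maxima.get(c.key.chromosome, 0), c.key.position)
    return GenomeLayout([(n, l) for n, l in sorted(maxima.items())])
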