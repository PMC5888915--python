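"""Shared fixtures: tiny genomes, call factories and small simulated crosses."""

from __future__ import annotations

import pytest

from afddmap import (
    CrossConfig,
    GenomeLayout,
    PoolCall,
    VariantClass,
    VariantKey,
    simulate_cross,
)


@pytest.fixture
def small_layout() -> GenomeLayout:
    return GenomeLayout([("chr1", 5_000_000), ("chr2", 3_500_000)])


@pytest.fixture
def make_call():
    """Factory for PoolCalls with sensible defaults."""

    def _make(
        chrom: str = "chr1",
        pos: int = 100,
        ref: str = "A",
        alt: str = "G",
        pool: str = "mutant",
        variant_reads: int = 12,
        coverage: int = 24,
        frequency: float | None = None,
        forward: int | None = None,
        reverse: int | None = None,
        unique_starts: int | None = None,
        variant_class: VariantClass = VariantClass.SNV,
    ) -> PoolCall:
        return PoolCall(
            key=VariantKey(chrom, pos, variant_class, ref, alt),
            pool_label=pool,
            variant_reads=variant_reads,
            coverage=coverage,
            frequency=(100.0 * variant_reads / coverage
                       if frequency is None else frequency),
            forward_reads=forward,
            reverse_reads=reverse,
            unique_start_positions=unique_starts,
        )

    return _make


def fully_linked_config(
    seg_type: str,
    seed: int,
    depth: float = 1000.0,
    variants_per_mb: float = 100.0,
    n_mutant: int = 17,
    n_wildtype: int = 16,
) -> CrossConfig:
    """A cross in which every variant is fully linked (r = 0) to the causal
    locus and in coupling phase: one chromosome, zero map distance per Mb.
    """
    layout = GenomeLayout([("chr1", 10_000_000)])
    return CrossConfig(
        layout=layout,
        causal_chromosome="chr1",
        causal_position=5_000_000,
        n_mutant_pool=n_mutant,
        n_wildtype_pool=n_wildtype,
        type_densities={seg_type: variants_per_mb},
        cM_per_Mb=0.0,
        depth_mean=depth,
        phase_linked_prob=1.0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def linked_type3_pools():
    """1000 fully linked <hk×hk> variants at depth 1000, pools 17/16."""
    cfg = fully_linked_config("<hk×hk>", seed=1)
    return simulate_cross(cfg)


@pytest.fixture(scope="session")
def linked_type2_pools():
    """1000 fully linked <lm×ll> variants at depth 1000, pools 17/16."""
    cfg = fully_linked_config("<lm×ll>", seed=1)
    return simulate_cross(cfg)
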