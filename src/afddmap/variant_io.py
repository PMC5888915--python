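"""Variant evidence I/O for pooled-sequencing (BSA-seq) analysis.

Each sequenced DNA pool contributes a set of variant calls with read-level
evidence (variant read count, coverage, strand counts, unique read start
positions).  This module reads those calls from single-sample VCFs or from a
tab-separated variant-table dialect emulating a variant-caller export, matches
variants across the two pools into pool-specific / common sets, and writes
tables, VCFs and BED region files.

Coordinates are 1-based inclusive internally (VCF convention); BED export
converts to 0-based half-open.  Multi-allelic records are always split into
biallelic :class:`PoolCall` objects before any downstream step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "VariantClass",
    "VariantKey",
    "PoolCall",
    "Membership",
    "BiPoolVariant",
    "GenomeLayout",
    "VariantIOError",
    "read_pool_vcf",
    "read_pool_table",
    "write_pool_table",
    "write_pool_vcf",
    "match_pools",
    "write_regions_bed",
]

log = logging.getLogger(__name__)

TOOL_TAG = "afddmap 0.1.0"

#: FORMAT tag used to carry the caller's "number of reads with unique start
#: positions" metric through VCF round trips.  Non-standard, hence documented.
USP_TAG = "USP"


class VariantIOError(ValueError):
    """Malformed or inconsistent variant input."""


class VariantClass(str, Enum):
    SNV = "SNV"
    MNV = "MNV"
    INSERTION = "insertion"
    DELETION = "deletion"
    REPLACEMENT = "replacement"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of one variant allele: site plus allele pair.

    Insertions use ``ref_allele == "-"`` and deletions ``alt_allele == "-"``
    (variant-table convention); VCF anchored alleles are normalized to this
    form on input so that keys join across file formats.
    """

    chromosome: str
    position: int  # 1-based
    variant_class: VariantClass
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise VariantIOError(f"position must be >= 1, got {self.position}")
        if self.alt_allele == self.ref_allele:
            raise VariantIOError(
                f"alt allele equals ref allele at {self.chromosome}:{self.position}"
            )


@dataclass
class PoolCall:
    """One variant allele observed in one pool, with read-level evidence."""

    key: VariantKey
    pool_label: str  # "mutant" or "wildtype"
    variant_reads: int
    coverage: int
    frequency: float  # percent in [0, 100]
    forward_reads: int | None = None
    reverse_reads: int | None = None
    unique_start_positions: int | None = None

    def __post_init__(self) -> None:
        if self.variant_reads > self.coverage:
            raise VariantIOError(
                f"variant reads ({self.variant_reads}) exceed coverage "
                f"({self.coverage}) at {self.key.chromosome}:{self.key.position}"
            )
        if min(self.variant_reads, self.coverage) < 0:
            raise VariantIOError("negative read counts")
        if not 0.0 <= self.frequency <= 100.0:
            raise VariantIOError(f"frequency {self.frequency} outside [0, 100]")
        if (
            self.forward_reads is not None
            and self.reverse_reads is not None
            and self.forward_reads + self.reverse_reads != self.variant_reads
        ):
            raise VariantIOError(
                "forward + reverse reads != variant reads at "
                f"{self.key.chromosome}:{self.key.position}"
            )


class Membership(str, Enum):
    MUTANT_SPECIFIC = "mutant_specific"
    WILDTYPE_SPECIFIC = "wildtype_specific"
    COMMON = "common"


@dataclass
class BiPoolVariant:
    """A variant matched across the two pools."""

    key: VariantKey
    mutant_call: PoolCall | None = None
    wildtype_call: PoolCall | None = None

    def __post_init__(self) -> None:
        if self.mutant_call is None and self.wildtype_call is None:
            raise VariantIOError("BiPoolVariant needs at least one pool call")

    @property
    def membership(self) -> Membership:
        if self.mutant_call is not None and self.wildtype_call is not None:
            return Membership.COMMON
        if self.mutant_call is not None:
            return Membership.MUTANT_SPECIFIC
        return Membership.WILDTYPE_SPECIFIC

    @property
    def afdd(self) -> float | None:
        """Allele frequency directional difference (mutant − wildtype), points."""
        if self.membership is not Membership.COMMON:
            return None
        return self.mutant_call.frequency - self.wildtype_call.frequency


@dataclass
class GenomeLayout:
    """Ordered chromosomes with lengths in bp."""

    chromosomes: list[tuple[str, int]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for name, length in self.chromosomes:
            if length <= 0:
                raise VariantIOError(f"chromosome {name} has non-positive length")
        self._index = {name: length for name, length in self.chromosomes}
        if len(self._index) != len(self.chromosomes):
            raise VariantIOError("duplicate chromosome names in layout")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def length_of(self, chromosome: str) -> int:
        try:
            return self._index[chromosome]
        except KeyError:
            raise VariantIOError(f"unknown chromosome {chromosome!r}") from None

    def __contains__(self, chromosome: str) -> bool:
        return chromosome in self._index

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _classify_vcf_alleles(pos: int, ref: str, alt: str) -> VariantKey | None:
    """Normalize one VCF REF/ALT pair to a dashed-dialect VariantKey.

    Returns None for symbolic/star alleles, which carry no sequence evidence.
    """
    if alt in {".", "*"} or alt.startswith("<"):
        return None
    if len(ref) == len(alt):
        cls = VariantClass.SNV if len(ref) == 1 else VariantClass.MNV
        return VariantKey(chromosome="", position=pos, variant_class=cls,
                          ref_allele=ref, alt_allele=alt)
    if len(ref) == 1 and len(alt) > 1 and alt[0] == ref:
        # anchored insertion: inserted bases follow the anchor base
        return VariantKey("", pos, VariantClass.INSERTION, "-", alt[1:])
    if len(alt) == 1 and len(ref) > 1 and ref[0] == alt:
        return VariantKey("", pos + 1, VariantClass.DELETION, ref[1:], "-")
    return VariantKey("", pos, VariantClass.REPLACEMENT, ref, alt)


def read_pool_vcf(
    path: str | Path,
    pool_label: str,
    layout: GenomeLayout | None = None,
) -> list[PoolCall]:
    """Read one pool's variant calls from a single-sample VCF.

    Requires per-sample ``DP`` and ``AD`` (falling back to INFO ``DP``);
    optional ``ADF``/``ADR`` give per-allele strand counts and the custom
    ``USP`` tag the unique-start-position count.  Multi-allelic records are
    split into one :class:`PoolCall` per alternate allele with
    ``frequency = 100 * AD_alt / DP``.
    """
    from cyvcf2 import VCF

    calls: list[PoolCall] = []
    vcf = VCF(str(path))
    for idx, rec in enumerate(vcf, start=1):
        if layout is not None and rec.CHROM not in layout:
            raise VariantIOError(
                f"{path}: record {idx} ({rec.CHROM}:{rec.POS}) on contig "
                f"{rec.CHROM!r} absent from the genome layout"
            )
        dp = None
        try:
            fmt_dp = rec.format("DP")
            if fmt_dp is not None:
                dp = int(fmt_dp[0][0])
        except KeyError:
            pass
        if dp is None or dp < 0:
            dp = rec.INFO.get("DP")
        if dp is None:
            raise VariantIOError(f"{path}: record {idx} ({rec.CHROM}:{rec.POS}) has no DP")
        ad = None
        try:
            fmt_ad = rec.format("AD")
            if fmt_ad is not None:
                ad = [int(x) for x in fmt_ad[0]]
        except KeyError:
            pass
        if ad is None:
            raise VariantIOError(f"{path}: record {idx} ({rec.CHROM}:{rec.POS}) has no AD")

        def _per_allele(tag: str) -> list[int] | None:
            try:
                arr = rec.format(tag)
            except KeyError:
                return None
            if arr is None:
                return None
            return [int(x) for x in arr[0]]

        adf = _per_allele("ADF")
        adr = _per_allele("ADR")
        usp = _per_allele(USP_TAG)

        for i, alt in enumerate(rec.ALT):
            key = _classify_vcf_alleles(rec.POS, rec.REF, alt)
            if key is None:
                continue
            key = replace(key, chromosome=rec.CHROM)
            vr = ad[i + 1] if len(ad) > len(rec.ALT) else ad[i]
            if dp <= 0:
                raise VariantIOError(
                    f"{path}: record {idx} ({rec.CHROM}:{rec.POS}) has DP={dp}"
                )
            def _alt_value(arr: list[int] | None) -> int | None:
                if arr is None:
                    return None
                # R-number arrays carry the reference allele first
                return arr[i + 1] if len(arr) > len(rec.ALT) else arr[i]

            fwd = _alt_value(adf)
            rev = _alt_value(adr)
            calls.append(
                PoolCall(
                    key=key,
                    pool_label=pool_label,
                    variant_reads=vr,
                    coverage=dp,
                    frequency=100.0 * vr / dp,
                    forward_reads=fwd,
                    reverse_reads=rev,
                    unique_start_positions=_alt_value(usp),
                )
            )
    return calls


TABLE_COLUMNS = [
    "chromosome", "position", "type", "reference", "allele",
    "count", "coverage", "frequency",
    "forward_reads", "reverse_reads", "unique_starts",
]
_REQUIRED_COLUMNS = TABLE_COLUMNS[:8]


def read_pool_table(path: str | Path, pool_label: str) -> list[PoolCall]:
    """Read the TSV variant-table dialect (variant-caller-export style).

    The declared ``frequency`` column is cross-checked against
    ``100 * count / coverage``; a discrepancy above 0.5 percentage points is
    logged as a warning and the recomputed value wins.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise VariantIOError(f"{path}: missing required columns {missing}")
    calls: list[PoolCall] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            cls = VariantClass(getattr(row, "type"))
            key = VariantKey(
                chromosome=str(row.chromosome),
                position=int(row.position),
                variant_class=cls,
                ref_allele=str(row.reference),
                alt_allele=str(row.allele),
            )
            count = int(row.count)
            coverage = int(row.coverage)
            declared = float(row.frequency)
        except (TypeError, ValueError, VariantIOError) as exc:
            raise VariantIOError(f"{path}: malformed row {row_no}: {exc}") from exc
        if coverage <= 0:
            raise VariantIOError(f"{path}: row {row_no}: non-positive coverage")
        recomputed = 100.0 * count / coverage
        if abs(declared - recomputed) > 0.5:
            log.warning(
                "%s row %d: declared frequency %.2f disagrees with "
                "count/coverage (%.2f); using recomputed value",
                path, row_no, declared, recomputed,
            )
            frequency = recomputed
        else:
            frequency = declared

        def _opt(row, name: str) -> int | None:
            val = getattr(row, name, None)
            if val is None or (isinstance(val, float) and pd.isna(val)) or val == "":
                return None
            return int(val)

        calls.append(
            PoolCall(
                key=key,
                pool_label=pool_label,
                variant_reads=count,
                coverage=coverage,
                frequency=frequency,
                forward_reads=_opt(row, "forward_reads"),
                reverse_reads=_opt(row, "reverse_reads"),
                unique_start_positions=_opt(row, "unique_starts"),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _header_comment(parameters: str = "") -> str:
    return f"# {TOOL_TAG}" + (f" | {parameters}" if parameters else "")


def write_pool_table(
    calls: Iterable[PoolCall], path: str | Path, parameters: str = ""
) -> None:
    """Write PoolCalls in the TSV dialect read by :func:`read_pool_table`."""
    rows = []
    for c in calls:
        rows.append({
            "chromosome": c.key.chromosome,
            "position": c.key.position,
            "type": c.key.variant_class.value,
            "reference": c.key.ref_allele,
            "allele": c.key.alt_allele,
            "count": c.variant_reads,
            "coverage": c.coverage,
            "frequency": repr(c.frequency),
            "forward_reads": "" if c.forward_reads is None else c.forward_reads,
            "reverse_reads": "" if c.reverse_reads is None else c.reverse_reads,
            "unique_starts": "" if c.unique_start_positions is None
            else c.unique_start_positions,
        })
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    with open(path, "w") as fh:
        fh.write(_header_comment(parameters) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_pool_vcf(
    calls: Sequence[PoolCall],
    path: str | Path,
    layout: GenomeLayout,
    sample_name: str | None = None,
) -> None:
    """Write a minimal valid single-sample VCF 4.2 for one pool.

    FORMAT carries DP, AD (ref,alt), and where present ADF/ADR/USP.  Dashed
    insertion/deletion keys are re-anchored with an ``N`` base, which is
    sufficient for round-tripping the key through :func:`read_pool_vcf`.
    """
    sample = sample_name or (calls[0].pool_label if calls else "pool")
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={TOOL_TAG}",
    ]
    for name, length in layout.chromosomes:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines += [
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=ADF,Number=R,Type=Integer,Description="Allelic depths, forward strand">',
        '##FORMAT=<ID=ADR,Number=R,Type=Integer,Description="Allelic depths, reverse strand">',
        f'##FORMAT=<ID={USP_TAG},Number=R,Type=Integer,'
        'Description="Reads with unique start positions supporting the allele">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    for c in sorted(calls, key=lambda c: (c.key.chromosome, c.key.position,
                                          c.key.alt_allele)):
        k = c.key
        if k.variant_class is VariantClass.INSERTION:
            pos, ref, alt = k.position, "N", "N" + k.alt_allele
        elif k.variant_class is VariantClass.DELETION:
            pos, ref, alt = k.position - 1, "N" + k.ref_allele, "N"
        else:
            pos, ref, alt = k.position, k.ref_allele, k.alt_allele
        fmt_keys = ["DP", "AD"]
        ref_reads = c.coverage - c.variant_reads
        fmt_vals = [str(c.coverage), f"{ref_reads},{c.variant_reads}"]
        if c.forward_reads is not None and c.reverse_reads is not None:
            fmt_keys += ["ADF", "ADR"]
            fmt_vals += [f"0,{c.forward_reads}", f"0,{c.reverse_reads}"]
        if c.unique_start_positions is not None:
            fmt_keys.append(USP_TAG)
            fmt_vals.append(f"0,{c.unique_start_positions}")
        lines.append(
            f"{k.chromosome}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t"
            + ":".join(fmt_keys) + "\t" + ":".join(fmt_vals)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Pool comparison
# ---------------------------------------------------------------------------

def match_pools(
    mutant: Iterable[PoolCall], wildtype: Iterable[PoolCall]
) -> list[BiPoolVariant]:
    """Exact-key join of the two pools' calls.

    A variant is *common* only when the full key (chromosome, position, class,
    ref, alt) matches; the same position with different alt alleles yields two
    pool-specific records.  Duplicate identical keys within one pool indicate
    an upstream multi-allelic-splitting bug and raise.
    """
    def _index(calls: Iterable[PoolCall], label: str) -> dict[VariantKey, PoolCall]:
        out: dict[VariantKey, PoolCall] = {}
        for c in calls:
            if c.key in out:
                raise VariantIOError(
                    f"duplicate key in {label} pool: "
                    f"{c.key.chromosome}:{c.key.position} {c.key.ref_allele}>"
                    f"{c.key.alt_allele}"
                )
            out[c.key] = c
        return out

    mut = _index(mutant, "mutant")
    wt = _index(wildtype, "wildtype")
    keys = sorted(set(mut) | set(wt))
    return [BiPoolVariant(key=k, mutant_call=mut.get(k), wildtype_call=wt.get(k))
            for k in keys]


def write_regions_bed(
    regions: Iterable[tuple[str, int, int, str, float]],
    path: str | Path,
    layout: GenomeLayout | None = None,
    parameters: str = "",
) -> None:
    """Write mapped regions as BED6.

    ``regions`` yields (chromosome, start, end, name, z) with 1-based
    inclusive bounds; output is 0-based half-open with
    ``score = round(z * 100)`` clamped to [0, 1000].
    """
    lines = [_header_comment(parameters)]
    for chrom, start, end, name, z in regions:
        if start < 1 or end < start:
            raise VariantIOError(f"bad interval {chrom}:{start}-{end}")
        if layout is not None and end > layout.length_of(chrom):
            raise VariantIOError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"({layout.length_of(chrom)} bp)"
            )
        score = max(0, min(1000, int(round(z * 100))))
        lines.append(f"{chrom}\t{start - 1}\t{end}\t{name}\t{score}\t.")
    Path(path).write_text("\n".join(lines) + "\n")
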