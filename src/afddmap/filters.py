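"""Two-stage variant filter cascade for pooled variant calls.

Stage one (``filter_primary``) removes artefact-prone calls right after
variant detection: reference-allele calls, hyperallelic sites, indels inside
reference homopolymer runs, sites whose reference base is an ambiguous IUPAC
code, and calls below the detection minima (coverage >= 10, variant reads
>= 2).  Stage two (``filter_confidence``) is applied after pool comparison
and keeps only high-confidence calls: coverage >= 20, forward/reverse read
balance within 0.25-0.5, and >= 5 reads with unique start positions.

Every removed call is attributed to the *first* failing filter in cascade
order, so the report's per-filter counts plus survivors always reconcile with
the input total.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

from .variant_io import PoolCall, VariantClass

__all__ = ["FilterConfig", "FilterReport", "filter_primary", "filter_confidence"]

log = logging.getLogger(__name__)

DEFAULT_AMBIGUOUS_CODES = frozenset("MRWSYK")


@dataclass
class FilterConfig:
    """Thresholds of both filter stages.

    balance is min(forward, reverse) / variant_reads on variant-supporting
    reads, so 0.5 means perfectly balanced strands.
    """

    min_coverage_primary: int = 10
    min_variant_reads: int = 2
    min_coverage_confidence: int = 20
    balance_min: float = 0.25
    balance_max: float = 0.5
    min_unique_starts: int = 5
    ambiguous_ref_codes: frozenset[str] = DEFAULT_AMBIGUOUS_CODES
    homopolymer_min_run: int = 4
    hyperallelic_min_alts: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.balance_min <= self.balance_max <= 0.5:
            raise ValueError("need 0 <= balance_min <= balance_max <= 0.5")
        for name in ("min_coverage_primary", "min_variant_reads",
                     "min_coverage_confidence", "min_unique_starts",
                     "homopolymer_min_run", "hyperallelic_min_alts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FilterReport:
    """Accounting of one filter stage: input = sum(removed) + surviving."""

    stage: str
    input_total: int = 0
    surviving: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    #: calls for which a metric was unavailable and its filter skipped
    skipped_metrics: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.input_total - sum(self.removed.values()) != self.surviving:
            raise AssertionError("filter report does not reconcile")

    def to_tsv(self) -> str:
        lines = [f"# filter stage: {self.stage}", "filter\tremoved"]
        lines += [f"{name}\t{n}" for name, n in self.removed.items()]
        lines.append(f"input\t{self.input_total}")
        lines.append(f"surviving\t{self.surviving}")
        for name, n in self.skipped_metrics.items():
            lines.append(f"skipped:{name}\t{n}")
        return "\n".join(lines) + "\n"


def _reference_base(
    reference_context: dict[str, str] | None, chromosome: str, position: int
) -> str | None:
    if reference_context is None:
        return None
    seq = reference_context.get(chromosome)
    if seq is None or not 1 <= position <= len(seq):
        return None
    return seq[position - 1].upper()


def _homopolymer_run_length(call: PoolCall, reference_context: dict[str, str]) -> int:
    """Length of the reference homopolymer run an indel call sits in.

    Measured for the single base the indel inserts or deletes; mixed-base
    indels return 0 (not homopolymer-slippage candidates).
    """
    key = call.key
    seq = reference_context.get(key.chromosome)
    if seq is None:
        return 0
    allele = key.alt_allele if key.variant_class is VariantClass.INSERTION \
        else key.ref_allele
    bases = set(allele.upper())
    if len(bases) != 1:
        return 0
    base = bases.pop()
    i = min(key.position - 1, len(seq) - 1)
    if seq[i].upper() != base:
        # anchor may sit just before the run (insertion anchoring); step right
        if i + 1 < len(seq) and seq[i + 1].upper() == base:
            i += 1
        else:
            return 0
    left = i
    while left > 0 and seq[left - 1].upper() == base:
        left -= 1
    right = i
    while right < len(seq) and seq[right].upper() == base:
        right += 1
    return right - left


def filter_primary(
    calls: list[PoolCall],
    reference_context: dict[str, str] | None = None,
    config: FilterConfig | None = None,
) -> tuple[list[PoolCall], FilterReport]:
    """Stage-one cascade, in order: reference-allele calls, hyperallelic
    sites, homopolymer indels, ambiguous reference bases, detection minima.

    ``reference_context`` maps chromosome name to reference sequence; without
    it the reference-allele and homopolymer filters are skipped with a
    warning (their inputs come from the reference, not the call).
    """
    config = config or FilterConfig()
    report = FilterReport(stage="primary", input_total=len(calls))
    order = ["reference_allele", "hyperallelic", "homopolymer",
             "ambiguous_reference", "detection_minima"]
    report.removed = {name: 0 for name in order}

    if reference_context is None:
        log.warning("no reference context: reference-allele and homopolymer "
                    "filters skipped")
        report.skipped_metrics["reference_context"] = len(calls)

    alts_per_site: dict[tuple[str, int], set[str]] = defaultdict(set)
    for c in calls:
        alts_per_site[(c.key.chromosome, c.key.position)].add(c.key.alt_allele)

    surviving: list[PoolCall] = []
    for c in calls:
        ref_base = _reference_base(reference_context, c.key.chromosome,
                                   c.key.position)
        if (
            ref_base is not None
            and c.key.variant_class is VariantClass.SNV
            and c.key.alt_allele.upper() == ref_base
        ):
            report.removed["reference_allele"] += 1
            continue
        if len(alts_per_site[(c.key.chromosome, c.key.position)]) \
                >= config.hyperallelic_min_alts:
            report.removed["hyperallelic"] += 1
            continue
        if (
            reference_context is not None
            and c.key.variant_class in (VariantClass.INSERTION,
                                        VariantClass.DELETION)
            and _homopolymer_run_length(c, reference_context)
            >= config.homopolymer_min_run
        ):
            report.removed["homopolymer"] += 1
            continue
        site_ref = ref_base if ref_base is not None else (
            c.key.ref_allele[0].upper() if c.key.ref_allele not in ("", "-")
            else None)
        if site_ref is not None and site_ref in config.ambiguous_ref_codes:
            report.removed["ambiguous_reference"] += 1
            continue
        if (c.coverage < config.min_coverage_primary
                or c.variant_reads < config.min_variant_reads):
            report.removed["detection_minima"] += 1
            continue
        surviving.append(c)

    report.surviving = len(surviving)
    report.check()
    return surviving, report


def filter_confidence(
    calls: list[PoolCall],
    config: FilterConfig | None = None,
) -> tuple[list[PoolCall], FilterReport]:
    """Stage-two high-confidence filter.

    Keeps calls with coverage >= 20, strand balance min(f,r)/(f+r) within
    [0.25, 0.5] (inclusive) and >= 5 unique read start positions.  A call
    missing the evidence for a metric skips that metric's filter (counted in
    the report) rather than failing.
    """
    config = config or FilterConfig()
    report = FilterReport(stage="confidence", input_total=len(calls))
    order = ["coverage", "strand_balance", "unique_starts"]
    report.removed = {name: 0 for name in order}
    report.skipped_metrics = {"strand_balance": 0, "unique_starts": 0}

    surviving: list[PoolCall] = []
    for c in calls:
        if min(c.variant_reads, c.coverage,
               c.forward_reads or 0, c.reverse_reads or 0,
               c.unique_start_positions or 0) < 0:
            raise ValueError("negative counts in confidence filter input")
        if c.coverage < config.min_coverage_confidence:
            report.removed["coverage"] += 1
            continue
        if c.forward_reads is None or c.reverse_reads is None:
            report.skipped_metrics["strand_balance"] += 1
        else:
            total = c.forward_reads + c.reverse_reads
            balance = (min(c.forward_reads, c.reverse_reads) / total
                       if total > 0 else 0.0)
            if not config.balance_min <= balance <= config.balance_max:
                report.removed["strand_balance"] += 1
                continue
        if c.unique_start_positions is None:
            report.skipped_metrics["unique_starts"] += 1
        elif c.unique_start_positions < config.min_unique_starts:
            report.removed["unique_starts"] += 1
            continue
        surviving.append(c)

    report.surviving = len(surviving)
    report.check()
    return surviving, report
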