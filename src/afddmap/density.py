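"""Genome-scan engine: moving-window profiles, per-Mb variant density and
z-score peak detection, specialized as MAFD and AFDDD mapping.

MAFD (mutant allele frequency and density) mapping scans the mutant-pool-
specific variants: regions whose variants average ~50% allele frequency and
cluster densely betray linkage to a dominant causal allele.  AFDDD (allele
frequency directional difference and density) mapping scans pool-common
variants whose frequency in the mutant pool exceeds the wildtype pool by at
least 30 percentage points; informative segregation types concentrate near a
directional difference of 50 points around the causal locus.

Density significance uses the standard score z = (X - mu) / sigma on variants
per Mb across fixed genome bins, with mu and the population standard
deviation taken over all bins genome-wide and an inclusive cutoff z >= 2.6
(two-tailed normal P ~ 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .variant_io import BiPoolVariant, GenomeLayout, Membership, PoolCall

__all__ = [
    "MappingResult",
    "moving_average",
    "bin_density",
    "z_test",
    "z_to_p",
    "merge_significant_regions",
    "mafd_map",
    "afddd_map",
    "DEFAULT_WINDOW",
    "DEFAULT_BIN_SIZE",
    "DEFAULT_Z_CUTOFF",
]

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 20
DEFAULT_BIN_SIZE = 1_000_000
DEFAULT_Z_CUTOFF = 2.6
DEFAULT_MAFD_BAND = (40.0, 60.0)
DEFAULT_AFDD_MIN = 30.0

PROFILE_COLUMNS = ["chromosome", "anchor", "mean_value", "window"]
BIN_COLUMNS = ["chromosome", "start", "end", "variant_count", "density",
               "z", "p", "significant"]
REGION_COLUMNS = ["chromosome", "start", "end", "name", "n_bins", "peak_z"]


@dataclass
class MappingResult:
    """Outcome of one MAFD or AFDDD scan."""

    method: str  # "MAFD" or "AFDDD"
    n_input: int
    n_selected: int
    profile: pd.DataFrame  # PROFILE_COLUMNS
    bins: pd.DataFrame  # BIN_COLUMNS
    regions: pd.DataFrame  # REGION_COLUMNS
    parameters: dict

    def region_rows(self):
        """Regions as (chrom, start, end, name, z) tuples for BED export."""
        return [
            (r.chromosome, int(r.start), int(r.end), r.name, float(r.peak_z))
            for r in self.regions.itertuples(index=False)
        ]


def moving_average(
    variants: pd.DataFrame, window: int = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Sliding mean of `value` over `window` consecutive variants, step 1.

    ``variants`` needs columns chromosome, position, value and must be sorted
    by (chromosome, position).  The window anchor is the mean position of its
    members; a chromosome with fewer than ``window`` variants yields no
    windows.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    required = {"chromosome", "position", "value"}
    if not required.issubset(variants.columns):
        raise ValueError(f"variants frame needs columns {sorted(required)}")
    for _, grp in variants.groupby("chromosome", sort=False):
        if not grp["position"].is_monotonic_increasing:
            raise ValueError("variants must be sorted by (chromosome, position)")
    out = []
    for chrom, grp in variants.groupby("chromosome", sort=False):
        if len(grp) < window:
            continue
        vals = grp["value"].to_numpy(dtype=float)
        pos = grp["position"].to_numpy(dtype=float)
        means = np.convolve(vals, np.ones(window) / window, mode="valid")
        anchors = np.convolve(pos, np.ones(window) / window, mode="valid")
        out.append(pd.DataFrame({
            "chromosome": chrom,
            "anchor": anchors,
            "mean_value": means,
            "window": window,
        }))
    if not out:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    return pd.concat(out, ignore_index=True)


def bin_density(
    positions: pd.DataFrame,
    layout: GenomeLayout,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Variant counts and per-Mb densities in fixed bins anchored at 1.

    Bins are non-overlapping [1, bin_size], [bin_size+1, 2*bin_size], ... on
    every layout chromosome; the final partial bin is scaled by its true
    length, and empty bins are kept (they enter the z-test baseline).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    rows = []
    grouped = dict(tuple(positions.groupby("chromosome", sort=False))) \
        if len(positions) else {}
    for name in grouped:
        if name not in layout:
            raise ValueError(f"variants on unknown chromosome {name!r}")
    for name, length in layout.chromosomes:
        n_bins = (length + bin_size - 1) // bin_size
        counts = np.zeros(n_bins, dtype=int)
        if name in grouped:
            pos = grouped[name]["position"].to_numpy(dtype=np.int64)
            if pos.min() < 1 or pos.max() > length:
                bad = pos[(pos < 1) | (pos > length)][0]
                raise ValueError(
                    f"variant at {name}:{bad} outside chromosome (1-{length})")
            counts = np.bincount((pos - 1) // bin_size, minlength=n_bins)
        starts = np.arange(n_bins, dtype=np.int64) * bin_size + 1
        ends = np.minimum(starts + bin_size - 1, length)
        lengths = ends - starts + 1
        rows.append(pd.DataFrame({
            "chromosome": name,
            "start": starts,
            "end": ends,
            "variant_count": counts,
            "density": counts * 1e6 / lengths,
        }))
    return pd.concat(rows, ignore_index=True)


def z_to_p(z: float) -> float:
    """Two-tailed normal p-value, p = 2 * (1 - Phi(|z|))."""
    return float(2.0 * stats.norm.sf(abs(z)))


def z_test(bins: pd.DataFrame, z_cutoff: float = DEFAULT_Z_CUTOFF) -> pd.DataFrame:
    """Annotate density bins with z = (X - mu) / sigma and significance.

    mu is the mean density over all bins genome-wide and sigma the population
    (divisor N) standard deviation; significance is inclusive (z >= cutoff).
    A degenerate scan (sigma = 0) sets every z to 0 with a warning.
    """
    if len(bins) < 2:
        raise ValueError("z-test needs at least 2 bins")
    out = bins.copy()
    density = out["density"].to_numpy(dtype=float)
    mu = density.mean()
    sigma = density.std(ddof=0)
    if sigma == 0.0:
        log.warning("all bins have identical density; z set to 0")
        z = np.zeros_like(density)
    else:
        z = (density - mu) / sigma
    out["z"] = z
    out["p"] = 2.0 * stats.norm.sf(np.abs(z))
    out["significant"] = out["z"] >= z_cutoff
    return out


def merge_significant_regions(bins: pd.DataFrame) -> pd.DataFrame:
    """Merge maximal runs of contiguous significant bins into regions.

    Bins are contiguous when adjacent on the same chromosome; no gap
    bridging.  Each region records its bin count and peak z.
    """
    runs: list[list] = []
    for _, grp in bins.groupby("chromosome", sort=False):
        run: list = []
        prev_end = None
        for row in grp.sort_values("start").itertuples(index=False):
            contiguous = prev_end is not None and row.start == prev_end + 1
            if row.significant:
                if run and not contiguous:
                    runs.append(run)
                    run = []
                run.append(row)
            elif run:
                runs.append(run)
                run = []
            prev_end = row.end
        if run:
            runs.append(run)
    rows = [
        {
            "chromosome": run[0].chromosome,
            "start": int(run[0].start),
            "end": int(run[-1].end),
            "name": f"region_{i}",
            "n_bins": len(run),
            "peak_z": float(max(r.z for r in run)),
        }
        for i, run in enumerate(runs, start=1)
    ]
    return pd.DataFrame(rows, columns=REGION_COLUMNS)


def _scan(
    selected: pd.DataFrame,
    all_values: pd.DataFrame,
    layout: GenomeLayout,
    method: str,
    n_input: int,
    window: int,
    bin_size: int,
    z_cutoff: float,
    parameters: dict,
) -> MappingResult:
    profile = moving_average(all_values, window=window) if len(all_values) else \
        pd.DataFrame(columns=PROFILE_COLUMNS)
    bins = bin_density(selected, layout, bin_size=bin_size)
    bins = z_test(bins, z_cutoff=z_cutoff)
    regions = merge_significant_regions(bins)
    return MappingResult(
        method=method,
        n_input=n_input,
        n_selected=len(selected),
        profile=profile,
        bins=bins,
        regions=regions,
        parameters=parameters,
    )


def mafd_map(
    mutant_specific: list[PoolCall],
    layout: GenomeLayout,
    band: tuple[float, float] = DEFAULT_MAFD_BAND,
    window: int = DEFAULT_WINDOW,
    bin_size: int = DEFAULT_BIN_SIZE,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
) -> MappingResult:
    """Mutant allele frequency and density mapping.

    The moving-average profile covers the allele frequencies of *all*
    mutant-pool-specific variants; the density/z scan runs on the subset with
    frequency inside ``band`` (inclusive; default 40-60%, bracketing the 50%
    expectation of fully linked type I variants).
    """
    lo, hi = band
    df = pd.DataFrame({
        "chromosome": [c.key.chromosome for c in mutant_specific],
        "position": [c.key.position for c in mutant_specific],
        "value": [c.frequency for c in mutant_specific],
    })
    order = {name: i for i, name in enumerate(layout.names)}
    if len(df):
        df["__ord"] = df["chromosome"].map(order)
        df = df.sort_values(["__ord", "position"]).drop(columns="__ord") \
            .reset_index(drop=True)
    selected = df[(df["value"] >= lo) & (df["value"] <= hi)] if len(df) else df
    if len(selected) == 0:
        log.warning("MAFD: no variants in frequency band [%s, %s]", lo, hi)
    return _scan(
        selected, df, layout, "MAFD", len(df), window, bin_size, z_cutoff,
        {"band": [lo, hi], "window": window, "bin_size": bin_size,
         "z_cutoff": z_cutoff},
    )


def afddd_map(
    common: list[BiPoolVariant],
    layout: GenomeLayout,
    afdd_min: float = DEFAULT_AFDD_MIN,
    window: int = DEFAULT_WINDOW,
    bin_size: int = DEFAULT_BIN_SIZE,
    z_cutoff: float = DEFAULT_Z_CUTOFF,
    reverse: bool = False,
) -> MappingResult:
    """Allele frequency directional difference and density mapping.

    AFDD = mutant frequency - wildtype frequency (signed percentage points);
    only variants with AFDD >= ``afdd_min`` (inclusive) enter the scan — the
    difference is strictly directional.  ``reverse=True`` swaps the pool
    roles for a control scan.
    """
    for v in common:
        if v.membership is not Membership.COMMON:
            raise ValueError("AFDDD mapping requires pool-common variants")
    sign = -1.0 if reverse else 1.0
    df = pd.DataFrame({
        "chromosome": [v.key.chromosome for v in common],
        "position": [v.key.position for v in common],
        "value": [sign * v.afdd for v in common],
    })
    order = {name: i for i, name in enumerate(layout.names)}
    if len(df):
        df["__ord"] = df["chromosome"].map(order)
        df = df.sort_values(["__ord", "position"]).drop(columns="__ord") \
            .reset_index(drop=True)
    selected = df[df["value"] >= afdd_min] if len(df) else df
    if len(selected) == 0:
        log.warning("AFDDD: no variants with AFDD >= %s", afdd_min)
    # profile over the selected set (the paper-style AFDD track)
    return _scan(
        selected.reset_index(drop=True), selected.reset_index(drop=True),
        layout, "AFDDD", len(df), window, bin_size, z_cutoff,
        {"afdd_min": afdd_min, "window": window, "bin_size": bin_size,
         "z_cutoff": z_cutoff, "reverse": reverse},
    )
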