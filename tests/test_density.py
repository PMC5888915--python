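"""Genome-scan engine: windows, bins, z-test, MAFD/AFDDD selection rules."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from afddmap import (
    BiPoolVariant,
    CrossConfig,
    GenomeLayout,
    afddd_map,
    bin_density,
    mafd_map,
    merge_significant_regions,
    moving_average,
    simulate_cross,
    z_test,
    z_to_p,
)


def frame(chrom_pos_val):
    return pd.DataFrame(chrom_pos_val, columns=["chromosome", "position", "value"])


class TestMovingAverage:
    def test_single_full_window(self):
        df = frame([("chr1", 10 * i, 50.0) for i in range(1, 21)])
        prof = moving_average(df, window=20)
        assert len(prof) == 1
        assert prof["mean_value"].iloc[0] == pytest.approx(50.0)
        assert prof["anchor"].iloc[0] == pytest.approx(df["position"].mean())

    def test_two_windows_from_21_variants(self):
        # first 20 values all 40 (mean 40); adding 80 shifts the mean to 42
        values = [40.0] * 20 + [80.0]
        df = frame([("chr1", i, v) for i, v in enumerate(values, start=1)])
        prof = moving_average(df, window=20)
        assert list(prof["mean_value"]) == pytest.approx([40.0, 42.0])

    def test_short_chromosome_yields_no_windows(self):
        df = frame([("chr1", i, 1.0) for i in range(19)] +
                   [("chr2", i, 2.0) for i in range(25)])
        prof = moving_average(df, window=20)
        assert set(prof["chromosome"]) == {"chr2"}

    def test_unsorted_input_rejected(self):
        df = frame([("chr1", 5, 1.0), ("chr1", 3, 1.0)])
        with pytest.raises(ValueError, match="sorted"):
            moving_average(df, window=1)

    def test_windows_never_span_chromosomes(self):
        df = frame([("chr1", i, 0.0) for i in range(1, 26)] +
                   [("chr2", i, 100.0) for i in range(1, 26)])
        prof = moving_average(df, window=20)
        assert set(prof["mean_value"]) == {0.0, 100.0}


class TestBinDensity:
    def test_full_and_partial_bins(self, small_layout):
        # 7 variants in chr1's first full Mb, 3 in chr2's terminal 0.5 Mb
        pos = [("chr1", p) for p in (1, 2, 3, 500_000, 999_998, 999_999, 1_000_000)]
        pos += [("chr2", p) for p in (3_100_000, 3_200_000, 3_499_999)]
        df = pd.DataFrame(pos, columns=["chromosome", "position"])
        bins = bin_density(df, small_layout)
        chr1_first = bins[(bins.chromosome == "chr1") & (bins.start == 1)].iloc[0]
        assert chr1_first["variant_count"] == 7
        assert chr1_first["density"] == pytest.approx(7.0)
        terminal = bins[(bins.chromosome == "chr2") & (bins.start == 3_000_001)].iloc[0]
        assert terminal["end"] == 3_500_000
        assert terminal["variant_count"] == 3
        assert terminal["density"] == pytest.approx(6.0)

    def test_empty_chromosome_bins_present(self, small_layout):
        df = pd.DataFrame([("chr1", 10)], columns=["chromosome", "position"])
        bins = bin_density(df, small_layout)
        chr2 = bins[bins.chromosome == "chr2"]
        assert len(chr2) == 4  # ceil(3.5 Mb / 1 Mb)
        assert (chr2["variant_count"] == 0).all()
        assert bins["variant_count"].sum() == 1

    def test_variant_beyond_chromosome_rejected(self, small_layout):
        df = pd.DataFrame([("chr2", 3_500_001)], columns=["chromosome", "position"])
        with pytest.raises(ValueError, match="outside"):
            bin_density(df, small_layout)

    def test_counts_conserved(self, small_layout):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "chromosome": rng.choice(["chr1", "chr2"], size=200),
            "position": rng.integers(1, 3_000_000, size=200),
        })
        bins = bin_density(df, small_layout)
        assert bins["variant_count"].sum() == 200


class TestZTest:
    def test_worked_example(self):
        bins = pd.DataFrame({
            "chromosome": "chr1", "start": np.arange(10) * 100 + 1,
            "end": np.arange(10) * 100 + 100,
            "variant_count": 0,
            "density": [2.0] * 9 + [20.0],
        })
        out = z_test(bins)
        # mu = 3.8, population sigma = 5.4, z(20) = 3.0
        assert out["z"].iloc[-1] == pytest.approx(3.0)
        assert bool(out["significant"].iloc[-1]) is True
        assert not out["significant"].iloc[:-1].any()

    def test_constant_density_gives_zero_z(self):
        bins = pd.DataFrame({"chromosome": "c", "start": [1, 101],
                             "end": [100, 200], "variant_count": 1,
                             "density": [5.0, 5.0]})
        out = z_test(bins)
        assert (out["z"] == 0).all()
        assert not out["significant"].any()

    def test_cutoff_is_inclusive(self):
        # nine equal bins plus one outlier give z = 3.0 exactly for the
        # outlier; a cutoff at exactly 3.0 must flag it (inclusive), one
        # infinitesimally above must not
        bins = pd.DataFrame({"chromosome": "c",
                             "start": np.arange(10) * 10 + 1,
                             "end": np.arange(10) * 10 + 10,
                             "variant_count": 0,
                             "density": [1.0] * 9 + [11.0]})
        out = z_test(bins, z_cutoff=3.0)
        assert out["z"].iloc[-1] == pytest.approx(3.0)
        assert bool(out["significant"].iloc[-1]) is True
        stricter = z_test(bins, z_cutoff=3.0 + 1e-9)
        assert bool(stricter["significant"].iloc[-1]) is False

    def test_fewer_than_two_bins_rejected(self):
        bins = pd.DataFrame({"chromosome": ["c"], "start": [1], "end": [10],
                             "variant_count": [0], "density": [1.0]})
        with pytest.raises(ValueError):
            z_test(bins)

    def test_reorder_invariance_and_centering(self):
        rng = np.random.default_rng(7)
        density = rng.poisson(5, size=40).astype(float)
        bins = pd.DataFrame({"chromosome": "c",
                             "start": np.arange(40) * 10 + 1,
                             "end": np.arange(40) * 10 + 10,
                             "variant_count": 0, "density": density})
        out = z_test(bins)
        shuffled = z_test(bins.sample(frac=1, random_state=1))
        merged = out.merge(shuffled, on="start", suffixes=("_a", "_b"))
        assert np.allclose(merged["z_a"], merged["z_b"])
        assert out["z"].mean() == pytest.approx(0.0, abs=1e-12)


class TestZToP:
    @pytest.mark.parametrize(
        ("z", "p"),
        [(2.9, 3.7e-3), (5.7, 1.2e-8), (3.4, 6.7e-4), (4.4, 1.1e-5)],
    )
    def test_reported_conversions(self, z, p):
        got = z_to_p(z)
        assert float(f"{got:.2g}") == pytest.approx(p)

    def test_zero_and_symmetry(self):
        assert z_to_p(0.0) == pytest.approx(1.0)
        assert z_to_p(-2.9) == z_to_p(2.9)


# ---------------------------------------------------------------------------
# Naive-oracle equivalence
# ---------------------------------------------------------------------------

def naive_moving_average(df, window):
    rows = []
    for chrom in df["chromosome"].unique():
        grp = df[df["chromosome"] == chrom]
        vals = list(grp["value"])
        pos = list(grp["position"])
        for i in range(len(vals) - window + 1):
            rows.append((chrom, sum(pos[i:i + window]) / window,
                         sum(vals[i:i + window]) / window))
    return rows


def naive_bin_density(df, layout, bin_size):
    rows = []
    for name, length in layout.chromosomes:
        start = 1
        while start <= length:
            end = min(start + bin_size - 1, length)
            n = sum(1 for _, r in df.iterrows()
                    if r["chromosome"] == name and start <= r["position"] <= end)
            rows.append((name, start, end, n, n * 1e6 / (end - start + 1)))
            start = end + 1
    return rows


def test_oracle_equivalence_on_small_fixture(small_layout):
    rng = np.random.default_rng(11)
    n = 100
    df = pd.DataFrame({
        "chromosome": np.sort(rng.choice(["chr1", "chr2"], size=n)),
        "position": 0,
        "value": rng.uniform(0, 100, size=n),
    })
    for chrom in ("chr1", "chr2"):
        k = (df["chromosome"] == chrom).sum()
        df.loc[df["chromosome"] == chrom, "position"] = np.sort(
            rng.choice(2_000_000, size=k, replace=False)) + 1

    prof = moving_average(df, window=7)
    naive = naive_moving_average(df, 7)
    assert len(prof) == len(naive)
    for (c, a, m), row in zip(naive, prof.itertuples(index=False)):
        assert row.chromosome == c
        assert row.anchor == pytest.approx(a)
        assert row.mean_value == pytest.approx(m)

    bins = bin_density(df, small_layout, bin_size=500_000)
    naive_bins = naive_bin_density(df, small_layout, 500_000)
    assert len(bins) == len(naive_bins)
    for (c, s, e, n_, d), row in zip(naive_bins, bins.itertuples(index=False)):
        assert (row.chromosome, row.start, row.end, row.variant_count) == (c, s, e, n_)
        assert row.density == pytest.approx(d)

    out = z_test(bins)
    dens = [d for *_, d in naive_bins]
    mu = sum(dens) / len(dens)
    sigma = math.sqrt(sum((x - mu) ** 2 for x in dens) / len(dens))
    for z, d in zip(out["z"], dens):
        assert z == pytest.approx((d - mu) / sigma)


# ---------------------------------------------------------------------------
# MAFD / AFDDD
# ---------------------------------------------------------------------------

class TestMafd:
    def test_full_band_equals_plain_density(self, small_layout, make_call):
        rng = np.random.default_rng(2)
        calls = [make_call(chrom="chr1", pos=int(p), variant_reads=int(v),
                           coverage=100)
                 for p, v in zip(np.sort(rng.choice(4_000_000, 50, replace=False)) + 1,
                                 rng.integers(1, 100, 50))]
        res = mafd_map(calls, small_layout, band=(0.0, 100.0))
        assert res.n_selected == len(calls)
        plain = bin_density(
            pd.DataFrame({"chromosome": [c.key.chromosome for c in calls],
                          "position": [c.key.position for c in calls]}),
            small_layout)
        assert (res.bins["variant_count"].to_numpy()
                == plain["variant_count"].to_numpy()).all()

    def test_band_selection_inclusive(self, small_layout, make_call):
        calls = [make_call(pos=10, variant_reads=40, coverage=100),
                 make_call(pos=20, variant_reads=60, coverage=100),
                 make_call(pos=30, variant_reads=61, coverage=100)]
        res = mafd_map(calls, small_layout, band=(40.0, 60.0))
        assert res.n_selected == 2

    def test_empty_band_selection_warns(self, small_layout, make_call, caplog):
        calls = [make_call(pos=10, variant_reads=90, coverage=100)]
        with caplog.at_level("WARNING"):
            res = mafd_map(calls, small_layout, band=(40.0, 60.0))
        assert res.n_selected == 0
        assert len(res.regions) == 0


class TestAfddd:
    def _variant(self, make_call, pos, mut_freq, wt_freq):
        mut = make_call(pos=pos, variant_reads=round(mut_freq), coverage=100,
                        frequency=mut_freq)
        wt = make_call(pos=pos, pool="wildtype", variant_reads=round(wt_freq),
                       coverage=100, frequency=wt_freq)
        return BiPoolVariant(key=mut.key, mutant_call=mut, wildtype_call=wt)

    def test_directional_selection(self, small_layout, make_call):
        common = [
            self._variant(make_call, 10, 82.0, 31.0),   # AFDD 51: selected
            self._variant(make_call, 20, 100.0, 50.0),  # ideal type II: 50
            self._variant(make_call, 30, 60.0, 30.0),   # exactly 30: inclusive
            self._variant(make_call, 40, 40.0, 70.0),   # -30: directional, out
        ]
        res = afddd_map(common, small_layout)
        assert res.n_selected == 3
        rev = afddd_map(common, small_layout, reverse=True)
        assert rev.n_selected == 1

    def test_pool_specific_input_rejected(self, small_layout, make_call):
        lone = BiPoolVariant(key=make_call().key, mutant_call=make_call())
        with pytest.raises(ValueError, match="common"):
            afddd_map([lone], small_layout)


class TestNullScan:
    """Under the null (no linked locus) false density peaks are rare and
    always isolated single bins, never the multi-bin clusters a real locus
    produces.  The z >= 2.6 cutoff is multiplicity-blind, so a small fraction
    of genome scans is still expected to show one marginal bin.
    """

    def test_unlinked_type_one_scan_is_mostly_clean(self):
        layout = GenomeLayout([("chr1", 12_000_000), ("chrC", 1_000_000)])
        scan_layout = GenomeLayout([("chr1", 12_000_000)])
        seeds_with_peaks = 0
        for seed in range(20):
            cfg = CrossConfig(
                layout=layout, causal_chromosome="chrC",
                causal_position=500_000,
                type_densities={"<lm×mm>": 40.0}, seed=seed)
            mutant, _, _ = simulate_cross(cfg)
            calls = [c for c in mutant if c.key.chromosome == "chr1"]
            res = mafd_map(calls, scan_layout)
            if len(res.regions):
                seeds_with_peaks += 1
                assert (res.regions["n_bins"] == 1).all()
        assert seeds_with_peaks <= 4


def test_region_merging_runs():
    bins = pd.DataFrame({
        "chromosome": ["c1"] * 5 + ["c2"] * 2,
        "start": [1, 101, 201, 301, 401, 1, 101],
        "end": [100, 200, 300, 400, 500, 100, 200],
        "variant_count": 0,
        "density": 0.0,
        "z": [3.0, 2.7, 1.0, 2.6, 3.5, 2.9, 0.1],
        "p": 0.0,
        "significant": [True, True, False, True, True, True, False],
    })
    regions = merge_significant_regions(bins)
    spans = [(r.chromosome, r.start, r.end, r.n_bins, r.peak_z)
             for r in regions.itertuples(index=False)]
    assert spans == [("c1", 1, 200, 2, 3.0), ("c1", 301, 500, 2, 3.5),
                     ("c2", 1, 100, 1, 2.9)]
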