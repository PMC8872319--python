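import itertools
import math

import numpy as np
import pytest

from sweepkit import diversity, simulate
from sweepkit.diversity import RohParams
from tests.conftest import matrix_from_haplotypes, random_matrix


# ------------------------------------------------------------------- site pi
class TestSitePi:
    def test_2_2(self):
        assert diversity.site_pi(2, 2) == pytest.approx(4 / 6)

    def test_monomorphic(self):
        assert diversity.site_pi(4, 0) == 0.0

    def test_3_1(self):
        assert diversity.site_pi(3, 1) == pytest.approx(0.5)

    def test_fewer_than_two_alleles_nan(self):
        assert math.isnan(diversity.site_pi(1, 0))


# -------------------------------------------------------------- windowed pi
def pi_oracle(gm, window_size):
    """Brute force: mean pairwise haplotype differences per window / length."""
    hap = gm.haplotypes()
    out = {}
    for chrom, sl in gm.chromosome_slices():
        n_windows = int(np.ceil(gm.chromosome_length(chrom) / window_size))
        for w in range(n_windows):
            lo, hi = w * window_size + 1, (w + 1) * window_size
            sites = np.flatnonzero((gm.chrom == chrom) & (gm.pos >= lo) & (gm.pos <= hi))
            total = 0.0
            for j in sites:
                col = hap[:, j]
                col = col[col >= 0]
                diffs = pairs = 0
                for a, b in itertools.combinations(col, 2):
                    pairs += 1
                    diffs += a != b
                if pairs:
                    total += diffs / pairs
            out[(chrom, w)] = total / window_size
    return out


class TestWindowedPi:
    def test_single_snp_in_200bp_window(self):
        # one site with pi 2/3 in a 200 bp window -> 0.003333
        hap = np.array([[0], [0], [1], [1]])
        gm = matrix_from_haplotypes(hap, [50], chrom_length=200)
        table = diversity.windowed_pi(gm, 200)
        assert table["pi"].iloc[0] == pytest.approx((4 / 6) / 200)

    def test_empty_window_zero_and_flagged(self):
        hap = np.array([[0], [0], [1], [1]])
        gm = matrix_from_haplotypes(hap, [50], chrom_length=400)
        table = diversity.windowed_pi(gm, 200)
        assert len(table) == 2
        assert table["pi"].iloc[1] == 0.0
        assert bool(table["empty"].iloc[1])
        assert not bool(table["empty"].iloc[0])

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            gm = random_matrix(
                rng,
                n_samples=int(rng.integers(2, 11)),
                n_variants=int(rng.integers(2, 21)),
                span=5_000,
            )
            table = diversity.windowed_pi(gm, 1_000)
            oracle = pi_oracle(gm, 1_000)
            for _, row in table.iterrows():
                w = (row["start"] - 1) // 1_000
                assert row["pi"] == pytest.approx(oracle[(row["chrom"], w)], abs=1e-12)

    def test_nonnegative_and_zero_on_monomorphic(self, rng):
        gm = random_matrix(rng, n_samples=4, n_variants=10)
        gm.alleles[:] = 0
        table = diversity.windowed_pi(gm, 10_000)
        assert (table["pi"] == 0).all()


# ---------------------------------------------------------------- Tajima's D
class TestTajimaConstants:
    def test_a1_n4(self):
        c = diversity.tajima_constants(4)
        assert c.a1 == pytest.approx(1 + 1 / 2 + 1 / 3)

    def test_n4_full_set(self):
        # independent evaluation of the printed formulas at n = 4
        n = 4
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        c = diversity.tajima_constants(4)
        assert c.a2 == pytest.approx(a2)
        assert c.b1 == pytest.approx(b1)
        assert c.b2 == pytest.approx(b2)
        assert c.c1 == pytest.approx(c1)
        assert c.c2 == pytest.approx(c2)
        assert c.e1 == pytest.approx(c1 / a1)
        assert c.e2 == pytest.approx(c2 / (a1**2 + a2))

    def test_a1_increasing(self):
        a1s = [diversity.tajima_constants(n).a1 for n in range(4, 30)]
        assert all(x < y for x, y in zip(a1s, a1s[1:]))

    def test_e_constants_positive(self):
        for n in range(4, 50):
            c = diversity.tajima_constants(n)
            assert c.e1 > 0 and c.e2 > 0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            diversity.tajima_constants(3)


class TestWindowedTajimaD:
    def test_zero_when_pi_equals_s_over_a1(self):
        # one singleton among 4 haplotypes: pi = 0.5, S/a1 = 1/1.8333 = 0.5454...
        # build a window where pi_hat == S/a1 by construction: impossible with
        # one site; use the numerator directly on a crafted two-site case.
        hap = np.array([[0, 0], [0, 0], [1, 0], [1, 1]])
        gm = matrix_from_haplotypes(hap, [10, 20], chrom_length=100)
        table = diversity.windowed_tajima_d(gm, 100)
        c = diversity.tajima_constants(4)
        S = 2
        pi_hat = diversity.site_pi(2, 2) + diversity.site_pi(3, 1)
        want = (pi_hat - S / c.a1) / math.sqrt(c.e1 * S + c.e2 * S * (S - 1))
        assert table["tajima_d"].iloc[0] == pytest.approx(want, abs=1e-12)

    def test_no_segregating_sites_missing(self):
        hap = np.zeros((4, 3), dtype=int)
        gm = matrix_from_haplotypes(hap, [10, 20, 30], chrom_length=100)
        table = diversity.windowed_tajima_d(gm, 100)
        assert math.isnan(table["tajima_d"].iloc[0])

    def test_neutral_mean_near_zero(self):
        cfg = simulate.SimulationConfig(
            n_samples=25, chrom_length=5_000_000, target_snp_count=5000, seed=42
        )
        gm = simulate.simulate_neutral(cfg, mode="independent")
        table = diversity.windowed_tajima_d(gm, 10_000)
        assert len(table) == 500
        assert -0.15 <= np.nanmean(table["tajima_d"]) <= 0.15

    def test_sweep_windows_negative(self):
        neg = 0
        for rep in range(20):
            cfg = simulate.SimulationConfig(
                n_samples=25, chrom_length=5_000_000, target_snp_count=3500,
                founder_haplotypes=16, switch_rate=2e-5, seed=300 + rep,
            )
            gm, _ = simulate.inject_sweep(
                simulate.simulate_neutral(cfg), "chr1", 2_000_001, 2_100_000, 0.8,
                seed=400 + rep,
            )
            table = diversity.windowed_tajima_d(gm, 100_000)
            d = table[table["start"] == 2_000_001]["tajima_d"].iloc[0]
            neg += d < 0
        assert neg >= 16


# ------------------------------------------------------------------------ ROH
def roh_track(states, spacing=100_000, start=1_000_000):
    """Build a 1-sample matrix from a genotype state string:
    o = homozygous, h = heterozygous, m = missing."""
    V = len(states)
    pos = start + spacing * np.arange(V)
    alleles = np.zeros((1, V, 2), dtype=np.int8)
    for j, s in enumerate(states):
        if s == "h":
            alleles[0, j] = [0, 1]
        elif s == "m":
            alleles[0, j] = [-1, -1]
    hap = alleles.reshape(1, V, 2)
    from sweepkit.genotypes import GenotypeMatrix

    return GenotypeMatrix(
        samples=["S0"],
        chrom=np.full(V, "chr1", dtype=object),
        pos=pos,
        ref=np.full(V, "A", dtype=object),
        alt=np.full(V, "C", dtype=object),
        alleles=hap,
        phased=True,
        chrom_lengths={"chr1": int(pos[-1]) + 1},
    )


class TestDetectRoh:
    def test_twenty_homozygous_snps_one_run(self):
        gm = roh_track("o" * 20, spacing=75_000)  # span 1.425 Mb < max_gap per step
        runs = diversity.detect_roh(gm, RohParams())
        assert len(runs) == 1
        assert runs["n_snps"].iloc[0] == 20
        assert runs["start"].iloc[0] == 1_000_000
        assert runs["end"].iloc[0] == 1_000_000 + 75_000 * 19

    def test_het_splits_run_below_min_snp(self):
        gm = roh_track("o" * 10 + "h" + "o" * 9, spacing=75_000)
        runs = diversity.detect_roh(gm, RohParams(max_opposite=0))
        assert len(runs) == 0  # segments of 10 and 9 < min_snp 15

    def test_het_tolerated_when_allowed(self):
        gm = roh_track("o" * 10 + "h" + "o" * 9, spacing=75_000)
        runs = diversity.detect_roh(gm, RohParams(max_opposite=1))
        assert len(runs) == 1
        assert runs["n_snps"].iloc[0] == 20

    def test_gap_terminates_run(self):
        V = 30
        pos = 1_000_000 + 75_000 * np.arange(V)
        pos[15:] += 2_000_000  # gap > 1 Mb between SNP 14 and 15
        gm = roh_track("o" * V, spacing=75_000)
        gm.pos = np.array(pos)
        runs = diversity.detect_roh(gm, RohParams())
        assert len(runs) == 2
        assert list(runs["n_snps"]) == [15, 15]

    def test_run_ends_trimmed_to_homozygous(self):
        gm = roh_track("o" * 16 + "h", spacing=75_000)
        runs = diversity.detect_roh(gm, RohParams(max_opposite=1))
        assert runs["end"].iloc[0] == 1_000_000 + 75_000 * 15

    def test_all_heterozygous_no_roh(self):
        gm = roh_track("h" * 40, spacing=10_000)
        runs = diversity.detect_roh(gm, RohParams())
        assert len(runs) == 0

    def test_injected_tract_recovered(self):
        cfg = simulate.SimulationConfig(
            n_samples=10, chrom_length=10_000_000, target_snp_count=5000,
            founder_haplotypes=32, switch_rate=5e-5, seed=77,
        )
        gm, truth = simulate.inject_roh(
            simulate.simulate_neutral(cfg), "S3", "chr1", 4_000_001, 5_000_000
        )
        s = gm.samples.index("S3")
        sites = np.flatnonzero((gm.pos >= truth.start) & (gm.pos <= truth.end))
        # flank the tract with heterozygous calls so its SNP-span is identifiable
        gm.alleles[s, sites[0] - 1] = [0, 1]
        gm.alleles[s, sites[-1] + 1] = [0, 1]
        first, last = int(gm.pos[sites[0]]), int(gm.pos[sites[-1]])
        runs = diversity.detect_roh(gm, RohParams(min_snp=40, min_length_bps=150_000))
        mine = runs[runs["sample"] == "S3"]
        covering = mine[(mine["start"] <= first) & (mine["end"] >= last)]
        assert len(covering) == 1
        assert covering["start"].iloc[0] == first
        assert covering["end"].iloc[0] == last


class TestFroh:
    def test_whole_chromosome_roh(self):
        gm = roh_track("o" * 20, spacing=75_000)
        runs = diversity.detect_roh(gm, RohParams())
        sample_df, _ = diversity.froh(runs, gm)
        assert sample_df["froh"].iloc[0] == pytest.approx(1.0)

    def test_one_tenth(self):
        import pandas as pd

        gm = roh_track("o" * 2, spacing=9_999_999)  # covered length 10 Mb
        runs = pd.DataFrame(
            [("S0", "chr1", 1_000_000, 1_999_999, 20, 1_000_000)],
            columns=["sample", "chrom", "start", "end", "n_snps", "length"],
        )
        sample_df, _ = diversity.froh(runs, gm)
        assert sample_df["froh"].iloc[0] == pytest.approx(0.1)

    def test_class_percentages_sum_to_100(self):
        import pandas as pd

        gm = roh_track("o" * 2, spacing=9_999_999)
        runs = pd.DataFrame(
            [
                ("S0", "chr1", 1, 500_000, 20, 500_000),
                ("S0", "chr1", 2_000_000, 5_000_000, 50, 3_000_001),
                ("S0", "chr1", 6_000_000, 15_000_000, 90, 9_000_001),
            ],
            columns=["sample", "chrom", "start", "end", "n_snps", "length"],
        )
        _, class_df = diversity.froh(runs, gm)
        assert class_df["pct"].sum() == pytest.approx(100.0)
        assert list(class_df["n_roh"]) == [1, 1, 0, 1]
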