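import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncscape.annotation import GeneRecord, GenomeAnnotation
from lncscape.chip import (
    DifferentialRegion,
    RegionLncLink,
    differential_windows,
    direction_consistency,
    link_regions,
    tss_profile,
)


def _grid(counts: list[int], chrom="chr1", width=100) -> pd.DataFrame:
    starts = np.arange(len(counts)) * width
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": starts + width, "count": counts}
    )


class TestTssProfile:
    def test_uniform_signal_is_flat(self):
        w = _grid([10] * 100)
        prof = tss_profile(w, [("chr1", 5000, "+")], flank=2000, n_bins=21)
        assert np.allclose(prof, prof[0])

    def test_center_bin_max_when_signal_at_tss(self):
        counts = [1] * 100
        counts[50] = 500
        prof = tss_profile(_grid(counts), [("chr1", 5050, "+")], flank=3000, n_bins=31)
        assert prof.argmax() == 15

    def test_minus_strand_profile_reversed(self):
        counts = [1] * 100
        counts[60] = 500  # 1 kb downstream of a TSS at 5050 on +
        plus = tss_profile(_grid(counts), [("chr1", 5050, "+")], flank=3000, n_bins=31)
        minus = tss_profile(_grid(counts), [("chr1", 5050, "-")], flank=3000, n_bins=31)
        assert np.allclose(plus, minus[::-1])

    def test_input_validation(self):
        w = _grid([1] * 10)
        with pytest.raises(ValueError):
            tss_profile(w, [], flank=100, n_bins=11)
        with pytest.raises(ValueError):
            tss_profile(w, [("chr1", 100, "+")], flank=100, n_bins=10)  # even
        with pytest.raises(ValueError):
            tss_profile(w, [("chr1", 100, "+")], flank=0, n_bins=11)


class TestDifferentialWindows:
    def test_gain_window_matches_likelihood_ratio_oracle(self):
        tumor = _grid([80] + [10] * 50)
        normal = _grid([5] + [10] * 50)
        regions = differential_windows(tumor, normal)
        assert len(regions) == 1
        r = regions[0]
        assert r.direction == "gain"
        # oracle: scipy G-test (log-likelihood ratio) on the 80-vs-5 window
        lt, ln = tumor["count"].sum(), normal["count"].sum()
        tot = 85
        exp = [tot * lt / (lt + ln), tot * ln / (lt + ln)]
        g_oracle, p_oracle = stats.power_divergence([80, 5], exp, lambda_="log-likelihood")
        et = tot * lt / (lt + ln)
        en = tot * ln / (lt + ln)
        g_ours = 2 * (80 * np.log(80 / et) + 5 * np.log(5 / en))
        assert g_ours == pytest.approx(g_oracle)
        assert stats.chi2.sf(g_ours, 1) == pytest.approx(p_oracle)

    def test_no_signal_no_regions(self):
        w = _grid([10] * 60)
        assert differential_windows(w, w.copy()) == []

    def test_fold_exactly_four_excluded(self):
        # strict fold cut: engineer summed normalized ratio exactly 4
        tumor = _grid([2000] + [10] * 400)
        normal = _grid([500] + [10] * 400)
        # equalize libraries so lib_ratio ~ 1; with pseudocount the ratio dips below 4
        regions = differential_windows(tumor, normal, fc_cut=4.0)
        strong = differential_windows(tumor, normal, fc_cut=3.9)
        assert regions == [] or all(abs(r.log2fc) > 2 for r in regions)
        assert len(strong) >= len(regions)

    def test_monotone_in_fold_cut(self):
        rng = np.random.default_rng(3)
        base = rng.poisson(10, 300)
        t = base.copy()
        t[[50, 150, 250]] = [120, 90, 60]
        tumor, normal = _grid(list(t)), _grid(list(base))
        prev = None
        for fc in (16, 8, 4, 2):
            got = {(r.start, r.end) for r in differential_windows(tumor, normal, fc_cut=fc)}
            if prev is not None:
                assert prev <= got
            prev = got

    def test_adjacent_same_direction_windows_merge(self):
        t = [10] * 30
        t[10] = t[11] = t[12] = 200
        regions = differential_windows(_grid(t), _grid([10] * 30))
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (1000, 1300)

    def test_grid_mismatch_errors(self):
        with pytest.raises(ValueError):
            differential_windows(_grid([1] * 5), _grid([1] * 6))


class TestLinkRegions:
    def _ann(self):
        return GenomeAnnotation(
            [
                GeneRecord("L1", "lncRNA", "chr1", 10_000, 12_000, "+"),   # TSS 10000
                GeneRecord("L2", "lncRNA", "chr1", 50_000, 52_000, "-"),   # TSS 51999
                GeneRecord("M1", "coding", "chr1", 30_000, 31_000, "+"),
            ]
        )

    def _de(self, sig):
        df = pd.DataFrame(
            {
                "log2fc": [sig.get(g, 0.0) for g in ["L1", "L2", "M1"]],
                "significant": [g in sig for g in ["L1", "L2", "M1"]],
            },
            index=["L1", "L2", "M1"],
        )
        df["direction"] = np.where(df["log2fc"] > 0, "up", "down")
        return df

    def test_gained_region_over_up_promoter_is_concordant(self):
        region = DifferentialRegion("chr1", 9000, 9400, 3.0, 0.001)
        links = link_regions([region], self._de({"L1": 2.0}), self._ann())
        assert len(links) == 1 and links[0].concordant

    def test_region_one_bp_outside_promoter_not_linked(self):
        # promoter of L1 = [7000, 13000); region ending at 7000 does not overlap
        region = DifferentialRegion("chr1", 6500, 7000, 3.0, 0.001)
        assert link_regions([region], self._de({"L1": 2.0}), self._ann()) == []
        region2 = DifferentialRegion("chr1", 6500, 7001, 3.0, 0.001)
        assert len(link_regions([region2], self._de({"L1": 2.0}), self._ann())) == 1

    def test_non_de_lncrna_not_linked(self):
        region = DifferentialRegion("chr1", 9000, 9400, 3.0, 0.001)
        assert link_regions([region], self._de({}), self._ann()) == []

    def test_matches_brute_force_overlap_on_random_fixtures(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            recs = []
            for i in range(15):
                s = int(rng.integers(0, 200_000))
                recs.append(
                    GeneRecord(f"L{i}", "lncRNA", "chr1", s, s + int(rng.integers(500, 3000)),
                               "+" if rng.random() < 0.5 else "-")
                )
            ann = GenomeAnnotation(recs)
            de = pd.DataFrame(
                {
                    "log2fc": rng.normal(0, 2, 15),
                    "significant": rng.random(15) < 0.6,
                },
                index=[f"L{i}" for i in range(15)],
            )
            de["direction"] = np.where(de["log2fc"] > 0, "up", "down")
            regions = [
                DifferentialRegion("chr1", s := int(rng.integers(0, 200_000)),
                                   s + int(rng.integers(200, 2000)),
                                   float(rng.normal(0, 3)), 0.01)
                for _ in range(10)
            ]
            links = link_regions(regions, de, ann, promoter_flank=3000)
            got = {(l.region.start, l.lnc_id) for l in links}
            exp = set()
            for r in regions:
                for g in de.index[de["significant"]]:
                    tss = ann[g].tss
                    if r.start < tss + 3000 and tss - 3000 < r.end:
                        exp.add((r.start, g))
            assert got == exp


class TestDirectionConsistency:
    def _links(self, pairs):
        return [
            RegionLncLink(DifferentialRegion("chr1", 0, 100, rf, 0.01), f"L{i}", rf, lf)
            for i, (rf, lf) in enumerate(pairs)
        ]

    def test_identical_fold_changes_give_r_one(self):
        r, p = direction_consistency(self._links([(1.0, 1.0), (2.0, 2.0), (-1.5, -1.5)]))
        assert r == pytest.approx(1.0)

    def test_anti_concordant_gives_minus_one(self):
        r, _ = direction_consistency(self._links([(1.0, -1.0), (2.0, -2.0), (-1.5, 1.5)]))
        assert r == pytest.approx(-1.0)

    def test_too_few_links_errors(self):
        with pytest.raises(ValueError):
            direction_consistency(self._links([(1.0, 1.0), (2.0, 2.0)]))
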