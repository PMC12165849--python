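"""QC metric oracles, knee calling, filter presets and saturation."""

import numpy as np
import pandas as pd
import pytest

from sumdemux.qc_metrics import (
    FilterProfile,
    Threshold,
    apply_filters,
    available_profiles,
    compute_qc,
    fraction_in_peaks,
    knee_call_cells,
    load_profile,
    promoter_ratio,
    saturation,
    tss_enrichment,
)


def _frags(rows):
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


# ---------------------------------------------------------------------------
# brute-force oracles: explicit per-position / per-fragment censuses


def brute_tss_score(frags, tss, center=50, flank=(1901, 2000)):
    insertions = []
    for _, r in frags.iterrows():
        insertions += [(r.contig, r.start), (r.contig, r.end - 1)]
    center_pos, flank_pos = set(), set()
    for contig, sites in tss.items():
        for t in sites:
            for p in range(t - center, t + center + 1):
                center_pos.add((contig, p))
            for p in range(t - flank[1], t - flank[0] + 1):
                flank_pos.add((contig, p))
            for p in range(t + flank[0], t + flank[1] + 1):
                flank_pos.add((contig, p))
    cc = sum(1 for i in insertions if i in center_pos)
    cf = sum(1 for i in insertions if i in flank_pos)
    return (cc / len(center_pos)) / ((cf + 1) / len(flank_pos))


def brute_interval_fraction(frags, intervals):
    n_in = 0
    for _, r in frags.iterrows():
        iv = intervals.get(r.contig, [])
        hit = any(a <= r.start < b or a <= r.end - 1 < b for a, b in iv)
        n_in += hit
    return n_in, n_in / len(frags) if len(frags) else 0.0


class TestTssEnrichment:
    tss = {"c": np.array([5_000, 40_000])}

    def test_all_insertions_in_center_matches_census(self):
        frags = _frags([("c", 4_960, 5_040), ("c", 4_990, 5_041),
                        ("c", 39_980, 40_020)])
        got = tss_enrichment(frags, self.tss)
        assert got == pytest.approx(brute_tss_score(frags, self.tss),
                                    rel=1e-12)

    def test_uniform_insertions_score_near_one(self, rng):
        starts = rng.integers(3_000, 95_000, 10_000)
        frags = pd.DataFrame({"contig": "c", "start": starts,
                              "end": starts + 100})
        tss = {"c": np.arange(6_000, 90_000, 6_000)}
        assert tss_enrichment(frags, tss) == pytest.approx(1.0, abs=0.2)

    def test_zero_fragments_scores_zero(self):
        assert tss_enrichment(_frags([]), self.tss) == 0.0

    def test_random_cells_match_census(self, rng):
        """Vectorised implementation agrees with the per-position census to
        near machine precision on random cells."""
        tss = {"c": np.sort(rng.choice(90_000, 5, replace=False) + 4_000)}
        for _ in range(25):
            n = int(rng.integers(1, 60))
            starts = rng.integers(0, 99_000, n)
            frags = pd.DataFrame({"contig": "c", "start": starts,
                                  "end": starts + rng.integers(30, 400, n)})
            assert tss_enrichment(frags, tss) == pytest.approx(
                brute_tss_score(frags, tss), rel=1e-9)


class TestFractionInPeaks:
    peaks = {"c": np.array([[150, 300]])}

    def test_end_insertion_inside_peak(self):
        n, frac = fraction_in_peaks(_frags([("c", 100, 200)]), self.peaks)
        assert (n, frac) == (1, 1.0)  # end-1 = 199 is inside [150, 300)

    def test_half_open_boundary_excluded(self):
        n, frac = fraction_in_peaks(_frags([("c", 100, 150)]), self.peaks)
        assert (n, frac) == (0, 0.0)  # insertion 149 < 150; 150 excluded

    def test_empty_peak_set(self):
        assert fraction_in_peaks(_frags([("c", 0, 10)]), {}) == (0, 0.0)

    def test_random_cells_match_census(self, rng):
        peaks = {"c": np.array([[1_000, 1_400], [5_000, 5_200],
                                [9_000, 9_800]])}
        iv = {"c": peaks["c"].tolist()}
        for _ in range(25):
            n = int(rng.integers(1, 50))
            starts = rng.integers(0, 10_000, n)
            frags = pd.DataFrame({"contig": "c", "start": starts,
                                  "end": starts + rng.integers(10, 500, n)})
            assert fraction_in_peaks(frags, peaks) == \
                brute_interval_fraction(frags, iv)

    def test_adding_in_peak_fragment_never_decreases_numerator(self, rng):
        peaks = {"c": np.array([[1_000, 1_400]])}
        frags = _frags([("c", 10, 200), ("c", 1_100, 1_200)])
        n0, _ = fraction_in_peaks(frags, peaks)
        more = pd.concat([frags, _frags([("c", 1_050, 1_300)])])
        n1, _ = fraction_in_peaks(more, peaks)
        assert n1 >= n0 + 1


class TestPromoterRatio:
    tss = {"c": np.array([10_000])}

    def test_distal_fragments_score_zero(self):
        assert promoter_ratio(_frags([("c", 20_000, 20_100)]), self.tss) == 0.0

    def test_all_in_promoter_scores_one(self):
        frags = _frags([("c", 9_000, 9_100), ("c", 10_050, 10_150)])
        assert promoter_ratio(frags, self.tss) == 1.0

    def test_mixed_cell_matches_census(self, rng):
        iv = {"c": [(8_000, 10_101)]}
        for _ in range(25):
            n = int(rng.integers(1, 50))
            starts = rng.integers(0, 30_000, n)
            frags = pd.DataFrame({"contig": "c", "start": starts,
                                  "end": starts + rng.integers(10, 400, n)})
            _, expected = brute_interval_fraction(frags, iv)
            assert promoter_ratio(frags, self.tss) == pytest.approx(
                expected, rel=1e-9)


class TestKneeCalling:
    @staticmethod
    def _mixture(seed, scale=1.0):
        rng = np.random.default_rng(seed)
        cells = rng.lognormal(np.log(1_000), 0.1, 500)
        ambient = rng.lognormal(np.log(10), 0.3, 5_000)
        counts = np.concatenate([cells, ambient]) * scale
        return pd.Series(counts.round().clip(1),
                         index=[f"bc{i}" for i in range(5_500)])

    def test_recovers_true_cell_count(self):
        k = knee_call_cells(self._mixture(42))
        assert abs(len(k.retained) - 500) <= 50

    def test_invariant_under_count_rescaling(self):
        k1 = knee_call_cells(self._mixture(42))
        k10 = knee_call_cells(self._mixture(42, scale=10))
        assert set(k1.retained) == set(k10.retained)

    def test_invariant_under_label_permutation(self):
        tot = self._mixture(42)
        shuffled = tot.sample(frac=1.0, random_state=0)
        k1 = knee_call_cells(tot)
        k2 = knee_call_cells(shuffled)
        assert set(k1.retained) == set(k2.retained)

    def test_flat_curve_falls_back_with_warning(self):
        tot = pd.Series(np.full(100, 7.0),
                        index=[f"b{i}" for i in range(100)])
        with pytest.warns(UserWarning, match="flat"):
            k = knee_call_cells(tot)
        assert k.fallback and len(k.retained) == 100

    def test_too_few_barcodes_rejected(self):
        with pytest.raises(ValueError, match="50"):
            knee_call_cells(pd.Series([5.0] * 10))


class TestFilterProfiles:
    def test_four_presets_shipped(self):
        assert available_profiles() == ["crispr", "macrophage", "species_mix",
                                        "tcell"]

    def test_macrophage_pass_example(self):
        qc = pd.DataFrame([{"cell": "S1:b", "n_fragments": 3_500,
                            "tss_score": 4.0, "promoter_ratio": 0.1,
                            "fip_fraction": 0.5, "droplet_occupancy": 3,
                            "n_genes": 200, "n_umi": 300, "pct_mito": 1.0}])
        out, _ = apply_filters(qc, load_profile("macrophage"))
        assert bool(out.pass_atac.item()) is True
        assert bool(out.pass_joint.item()) is True

    def test_macrophage_tss_boundary_fails(self):
        qc = pd.DataFrame([{"cell": "S1:b", "n_fragments": 3_500,
                            "tss_score": 2.9, "promoter_ratio": 0.1,
                            "droplet_occupancy": 3, "n_genes": 200}])
        out, summary = apply_filters(qc, load_profile("macrophage"))
        assert bool(out.pass_atac.item()) is False
        assert summary["fail_atac_min_tss"] == 1

    def test_strict_thresholds_are_strict(self):
        # macrophage fragments filter is > 3000, not >=
        qc = pd.DataFrame([{"cell": "S1:b", "n_fragments": 3_000,
                            "tss_score": 5.0, "promoter_ratio": 0.1,
                            "droplet_occupancy": 1, "n_genes": 200}])
        out, _ = apply_filters(qc, load_profile("macrophage"))
        assert bool(out.pass_atac.item()) is False

    def test_empty_profile_passes_everything(self):
        qc = pd.DataFrame([{"cell": "S1:b", "n_fragments": 1}])
        out, _ = apply_filters(qc, FilterProfile(name="none"))
        assert bool(out.pass_joint.item()) is True

    def test_tightening_never_increases_pass_count(self):
        rng = np.random.default_rng(5)
        qc = pd.DataFrame({
            "cell": [f"S1:b{i}" for i in range(200)],
            "n_fragments": rng.integers(100, 5_000, 200),
            "tss_score": rng.uniform(0, 10, 200),
        })
        passes = []
        for min_frag in (500, 1_000, 2_000):
            prof = FilterProfile(name="t",
                                 atac={"min_fragments": Threshold(min_frag)})
            out, _ = apply_filters(qc, prof)
            passes.append(int(out.pass_atac.sum()))
        assert passes == sorted(passes, reverse=True)

    def test_overrides(self):
        prof = load_profile("species_mix",
                            overrides={"atac": {"min_fragments":
                                                {"value": 10,
                                                 "inclusive": True}}})
        assert prof.atac["min_fragments"].value == 10

    def test_unknown_threshold_rejected(self):
        with pytest.raises(ValueError, match="unknown threshold"):
            FilterProfile(name="bad", atac={"min_wombats": Threshold(1)})


class TestComputeQc:
    def test_counts_and_fractions(self, ref_small):
        contig = next(iter(ref_small.contigs))
        frags = pd.DataFrame({
            "contig": contig,
            "start": [100, 200, 300], "end": [400, 500, 600],
            "sample": "S1", "droplet": "bc1", "dup_count": 1,
        })
        mol = pd.DataFrame({"cell": ["S1:bc1"] * 2,
                            "gene": ref_small.genes.name.iloc[:2],
                            "n_molecules": [3, 2]})
        cat = dict(zip(ref_small.genes.name, ref_small.genes.category))
        qc = compute_qc(frags, mol, ref_small.tss, ref_small.peaks,
                        gene_categories=cat)
        row = qc.iloc[0]
        assert row.n_fragments == 3
        assert row.n_umi == 5 and row.n_genes == 2
        assert row.pct_mito == 100.0  # first two toy genes are mito-like
        assert row.droplet_occupancy == 1
        assert 0 <= row.fip_fraction <= 1 and row.n_fip <= row.n_fragments


class TestSaturation:
    def test_worked_example(self):
        assert saturation(30_000, 10_200) == pytest.approx(0.66)

    def test_all_unique_is_zero(self):
        assert saturation(1_000, 1_000) == 0.0

    def test_every_read_duplicated_once_is_half(self):
        assert saturation(2_000, 1_000) == 0.5

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            saturation(0, 0)
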