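"""Count matrices, metagene profiles, smoothing and peak localisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tssnuc.model import Gene, NucleosomeSite, RESISTANT, SENSITIVE
from tssnuc.profiles import (
    AverageProfile,
    PositionCountMatrix,
    average_profile,
    build_count_matrix,
    find_peaks,
    moving_mean,
    tss_offset,
)


class TestTssOffset:
    @pytest.mark.parametrize(
        "center,tss,strand,expected",
        [
            (1135, 1000, "+", 135),
            (965, 1000, "-", 35),
            (1000, 1000, "+", 0),
            (1000, 1000, "-", 0),
            (965, 1000, "+", -35),
        ],
    )
    def test_offset_arithmetic(self, center, tss, strand, expected):
        assert tss_offset(center, tss, strand) == expected


def _site(center, chrom="2L", sens=RESISTANT):
    return NucleosomeSite(chrom, center - 73, center + 74, sens)


class TestCountMatrix:
    def test_plus_strand_placement(self):
        gene = Gene("g1", "2L", 1000, "+", 1.0, ())
        sites = [_site(1135), _site(965)]
        m = build_count_matrix([gene], sites)
        assert m.counts[0, list(m.offsets).index(135)] == 1
        assert m.counts[0, list(m.offsets).index(-35)] == 1
        assert m.counts.sum() == 2

    def test_minus_strand_reflection(self):
        gene = Gene("g1", "2L", 1000, "-", 1.0, ())
        m = build_count_matrix([gene], [_site(1135), _site(965)])
        assert m.counts[0, list(m.offsets).index(-135)] == 1
        assert m.counts[0, list(m.offsets).index(35)] == 1

    def test_multiplicity_preserved(self):
        gene = Gene("g1", "2L", 1000, "+", 1.0, ())
        m = build_count_matrix([gene], [_site(1135), _site(1135)])
        assert m.counts[0, list(m.offsets).index(135)] == 2

    def test_gene_without_sites_gets_zero_row(self):
        genes = [Gene("g1", "4", 1000, "+", 1.0, ())]
        m = build_count_matrix(genes, [_site(1135, chrom="2L")])
        assert m.counts.sum() == 0

    def test_sites_outside_window_ignored(self):
        gene = Gene("g1", "2L", 1000, "+", 1.0, ())
        m = build_count_matrix([gene], [_site(1000 + 200), _site(1000 - 301)])
        assert m.counts.sum() == 0
        inside = build_count_matrix([gene], [_site(1000 + 199), _site(1000 - 300)])
        assert inside.counts.sum() == 2

    def test_mixed_sensitivities_rejected(self):
        gene = Gene("g1", "2L", 1000, "+", 1.0, ())
        with pytest.raises(ValueError):
            build_count_matrix([gene], [_site(1100), _site(1050, sens=SENSITIVE)])

    def test_conservation_of_total_counts(self, default_dataset):
        """Sum of mean_count x n_genes equals in-window (gene, site) pairs."""
        m = default_dataset["matrices"][RESISTANT]
        prof = average_profile(m)
        assert prof.mean_count.sum() * prof.n_genes == pytest.approx(m.counts.sum())

    @settings(max_examples=30, deadline=None)
    @given(
        tss=st.integers(1000, 2000),
        centers=st.lists(st.integers(800, 2300), max_size=20),
    )
    def test_mirror_symmetry(self, tss, centers):
        """Reflecting coordinates and flipping strand leaves counts unchanged."""
        mirror = 4000
        g_plus = Gene("g", "2L", tss, "+", 1.0, ())
        g_minus = Gene("g", "2L", mirror - tss, "-", 1.0, ())
        sites = [_site(c) for c in centers]
        m_sites = [_site(mirror - c) for c in centers]
        m1 = build_count_matrix([g_plus], sites)
        m2 = build_count_matrix([g_minus], m_sites)
        assert np.array_equal(m1.counts, m2.counts)


class TestMovingMean:
    def test_shrinking_edges(self):
        assert moving_mean([0, 3, 6], 3).tolist() == [1.5, 3.0, 4.5]

    def test_constant_vector_unchanged(self):
        assert moving_mean([2.0] * 7, 3).tolist() == [2.0] * 7

    def test_window_one_is_identity(self):
        v = [3.0, 1.0, 4.0, 1.0, 5.0]
        assert moving_mean(v, 1).tolist() == v

    @pytest.mark.parametrize("window", [0, 2, 4])
    def test_even_or_zero_window_rejected(self, window):
        with pytest.raises(ValueError):
            moving_mean([1.0, 2.0], window)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            moving_mean([], 3)

    def test_nan_values_skipped(self):
        out = moving_mean([1.0, np.nan, 3.0], 3)
        assert out[0] == 1.0 and out[1] == 2.0 and out[2] == 3.0

    def test_total_preserved_up_to_edge_shrinkage(self, rng):
        v = rng.poisson(5, 100).astype(float)
        assert moving_mean(v, 1).sum() == v.sum()
        # window 3: any discrepancy comes from the two shrunk edge windows
        diff = abs(moving_mean(v, 3).sum() - v.sum())
        assert diff <= v[0] + v[1] + v[-1] + v[-2]


def _profile(values, start=-300):
    v = np.asarray(values, dtype=float)
    offs = np.arange(start, start + len(v))
    return AverageProfile(offsets=offs, mean_count=v, smoothed=v, n_genes=1)


class TestFindPeaks:
    def test_single_planted_bump(self):
        offs = np.arange(-300, 200)
        v = np.exp(-((offs - 135) ** 2) / 450.0)
        prof = AverageProfile(offsets=offs, mean_count=v, smoothed=v, n_genes=1)
        assert find_peaks(prof, (0, 199), 1) == [135]

    def test_monotone_profile_has_no_peak(self):
        prof = _profile(np.linspace(0, 1, 500))
        assert find_peaks(prof, (-299, 198), 3) == []

    def test_equal_height_tie_broken_toward_zero_then_negative(self):
        v = np.zeros(500)
        offs = np.arange(-300, 200)
        v[list(offs).index(-185)] = 1.0
        v[list(offs).index(-35)] = 1.0
        prof = AverageProfile(offsets=offs, mean_count=v, smoothed=v, n_genes=1)
        assert find_peaks(prof, (-299, 0), 2) == [-35, -185]

    def test_shoulder_maxima_suppressed_within_min_distance(self):
        v = np.zeros(500)
        offs = np.arange(-300, 200)
        v[list(offs).index(135)] = 2.0
        v[list(offs).index(140)] = 1.5  # shoulder of the same nucleosome
        v[list(offs).index(35)] = 1.0
        prof = AverageProfile(offsets=offs, mean_count=v, smoothed=v, n_genes=1)
        assert find_peaks(prof, (0, 199), 2) == [135, 35]
        assert find_peaks(prof, (0, 199), 2, min_distance=0) == [135, 140]


class TestAverageProfile:
    def test_column_means(self):
        m = PositionCountMatrix(
            gene_ids=["a", "b"],
            offsets=np.array([0, 1]),
            counts=np.array([[0, 1], [0, 1]]),
            sensitivity=RESISTANT,
        )
        prof = average_profile(m)
        assert prof.mean_count.tolist() == [0.0, 1.0]

    def test_single_row_identity(self):
        m = PositionCountMatrix(
            gene_ids=["a"],
            offsets=np.array([0, 1, 2]),
            counts=np.array([[3, 1, 4]]),
            sensitivity=RESISTANT,
        )
        assert average_profile(m).mean_count.tolist() == [3.0, 1.0, 4.0]

    def test_zero_genes_rejected(self):
        m = PositionCountMatrix(
            gene_ids=[], offsets=np.array([0]), counts=np.zeros((0, 1)), sensitivity=""
        )
        with pytest.raises(ValueError):
            average_profile(m)

    def test_uniform_placement_gives_flat_profile(self, default_dataset):
        """Delocalised (NonActive) nucleosomes: max/min of the smoothed
        profile approaches 1 for thousands of genes."""
        table = default_dataset["classification"].table
        ids = table.loc[table["chromatin_class"] == "NonActive", "gene_id"].tolist()
        m = default_dataset["matrices"][RESISTANT].subset(ids)
        prof = average_profile(m)
        ratio = prof.smoothed.max() / prof.smoothed.min()
        assert ratio < 1.2

    def test_planted_nuc1_recovered_in_downstream_window(self, default_dataset):
        """Smoothed Active-class profile peaks at the planted Nuc+1 offset."""
        table = default_dataset["classification"].table
        ids = table.loc[table["chromatin_class"] == "Active", "gene_id"].tolist()
        prof = average_profile(default_dataset["matrices"][RESISTANT].subset(ids))
        (peak,) = find_peaks(prof, (1, 199), 1)
        assert abs(peak - 135) <= 3
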