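"""Kendall tau, its normal-approximation significance, and the offset scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tssnuc.correlation import kendall_tau, scan, scan_by_class, tau_variance
from tssnuc.model import RESISTANT, SENSITIVE
from tssnuc.profiles import PositionCountMatrix


def brute_force_tau_b(x, y):
    """O(n^2) pair-enumeration oracle for tau-b: every pair (i, j) is
    classified as concordant, discordant, or tied in x and/or y."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    concordant = discordant = tied_x = tied_y = 0
    for i in range(n - 1):
        dx = x[i] - x[i + 1 :]
        dy = y[i] - y[i + 1 :]
        tied_x += int(np.sum(dx == 0))
        tied_y += int(np.sum(dy == 0))
        concordant += int(np.sum(dx * dy > 0))
        discordant += int(np.sum(dx * dy < 0))
    pairs = n * (n - 1) // 2
    denom = np.sqrt((pairs - tied_x) * (pairs - tied_y))
    return (concordant - discordant) / denom if denom > 0 else np.nan


class TestKendallTau:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 1 / 3),  # C=4, D=2, no ties
        ],
    )
    def test_known_values(self, x, y, expected):
        assert kendall_tau(x, y) == pytest.approx(expected)

    def test_all_tied_vector_is_undefined(self):
        assert np.isnan(kendall_tau([1, 1, 1], [1, 2, 3]))
        assert np.isnan(kendall_tau([1, 2, 3], [5, 5, 5]))

    def test_short_or_mismatched_input_rejected(self):
        with pytest.raises(ValueError):
            kendall_tau([1], [1])
        with pytest.raises(ValueError):
            kendall_tau([1, 2], [1, 2, 3])

    def test_matches_brute_force_oracle_on_tied_vectors(self, rng):
        """Exact agreement with O(n^2) pair counting on random tied data."""
        for _ in range(300):
            n = rng.integers(2, 51)
            x = rng.integers(0, 5, n).astype(float)  # heavy ties, like counts
            y = rng.lognormal(0, 1, n).round(1)
            expected = brute_force_tau_b(x, y)
            got = kendall_tau(x, y)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(0, 6), min_size=3, max_size=25),
        st.data(),
    )
    def test_antisymmetry_and_monotone_invariance(self, xs, data):
        ys = data.draw(
            st.lists(
                st.floats(-50, 50, allow_nan=False),
                min_size=len(xs),
                max_size=len(xs),
            )
        )
        t = kendall_tau(xs, ys)
        neg = kendall_tau(xs, [-v for v in ys])
        if np.isnan(t):
            assert np.isnan(neg)
        else:
            assert neg == pytest.approx(-t, abs=1e-12)
            # strictly monotone transforms of either argument preserve tau
            assert kendall_tau([3 * v + 1 for v in xs], ys) == pytest.approx(t, abs=1e-12)
            assert kendall_tau(xs, [np.expm1(v / 50) for v in ys]) == pytest.approx(
                t, abs=1e-12
            )


class TestTauVariance:
    def test_exact_values(self):
        assert tau_variance(2) == 1.0
        assert tau_variance(10) == pytest.approx(50 / 810, abs=0, rel=1e-15)

    def test_large_n_limit(self):
        # n * D -> 4/9
        assert 1_000_000 * tau_variance(1_000_000) == pytest.approx(4 / 9, rel=1e-5)

    def test_strictly_decreasing_in_n(self):
        values = [tau_variance(n) for n in range(2, 200)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tau_variance(1)


def _matrix(counts, sens=RESISTANT):
    counts = np.asarray(counts)
    return PositionCountMatrix(
        gene_ids=[f"g{i}" for i in range(counts.shape[0])],
        offsets=np.arange(counts.shape[1]),
        counts=counts,
        sensitivity=sens,
    )


class TestScan:
    def test_constant_covariate_gives_all_missing(self, rng):
        m = _matrix(rng.poisson(2, (20, 5)))
        prof = scan(m, np.ones(20))
        assert np.isnan(prof.tau).all()
        assert not prof.significant.any()

    def test_column_matching_covariate_ranks_gives_tau_one(self, rng):
        cov = rng.permutation(30).astype(float)
        counts = np.tile(cov[:, None], (1, 3)).astype(int)
        prof = scan(_matrix(counts), cov)
        assert prof.tau == pytest.approx([1.0, 1.0, 1.0])

    def test_all_zero_column_is_missing_not_significant(self, rng):
        counts = rng.poisson(2, (50, 3))
        counts[:, 1] = 0
        prof = scan(_matrix(counts), rng.lognormal(0, 1, 50))
        assert np.isnan(prof.tau[1])
        assert not prof.significant[1]

    def test_bonferroni_mask_uses_alpha_over_m(self, rng):
        cov = np.arange(100, dtype=float)
        counts = np.tile(np.arange(100)[:, None], (1, 2)).astype(int)
        prof = scan(_matrix(counts), cov, alpha=0.05, m=500)
        assert prof.significant.all()
        assert prof.m == 500

    def test_z_uses_classical_variance(self, rng):
        counts = rng.poisson(8, (40, 2))
        cov = rng.lognormal(0, 1, 40)
        prof = scan(_matrix(counts), cov)
        sd = np.sqrt(tau_variance(40))
        assert prof.z == pytest.approx(prof.tau / sd, nan_ok=True)

    def test_tie_corrected_variant_is_more_conservative_under_ties(self, rng):
        counts = rng.poisson(0.5, (80, 10))  # heavily tied columns
        cov = rng.lognormal(0, 1, 80)
        classical = scan(_matrix(counts), cov)
        corrected = scan(_matrix(counts), cov, tie_corrected=True)
        ok = np.isfinite(classical.p) & np.isfinite(corrected.p)
        # the classical no-ties variance understates the null spread of tau-b,
        # so its p-values are systematically smaller
        assert np.median(corrected.p[ok] - classical.p[ok]) > 0

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            scan(_matrix(np.zeros((1, 3), dtype=int)), np.ones(1))


class TestScanByClass:
    def test_profile_combinatorics(self, default_dataset):
        """2 chromatin classes x 3 strata x 2 sensitivities -> 12 profiles."""
        profiles = scan_by_class(
            default_dataset["classification"].table,
            default_dataset["matrices"],
            covariate="RPKM",
            stratifier="boe_class",
        )
        assert len(profiles) == 12
        labels = {
            (p.labels["chromatin_class"], p.labels["stratum"], p.labels["sensitivity"])
            for p in profiles
        }
        assert len(labels) == 12

    def test_covariate_equal_to_stratifier_axis_rejected(self, default_dataset):
        with pytest.raises(ValueError):
            scan_by_class(
                default_dataset["classification"].table,
                default_dataset["matrices"],
                covariate="RPKM",
                stratifier="rpkm_class",
            )

    def test_permuted_covariate_destroys_planted_significance(self, default_dataset, rng):
        """Permutation smoke test: no significant runs survive."""
        table = default_dataset["classification"].table
        sub = table[
            (table["chromatin_class"] == "Active")
            & (table["boe_class"] == "TissueSpecific")
        ]
        m = default_dataset["matrices"][RESISTANT].subset(sub["gene_id"].tolist())
        cov = sub["rpkm_s2"].to_numpy()
        planted = scan(m, cov)
        assert planted.significant_runs(min_length=3)
        permuted = scan(m, rng.permutation(cov))
        assert permuted.significant_runs(min_length=3) == []
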