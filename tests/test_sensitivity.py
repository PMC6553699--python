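import itertools

import numpy as np
import pandas as pd
import pytest

from plaquemap.binning import ProjectionParams
from plaquemap.centerline import compute_centerline
from plaquemap.phantom import PhantomSpec, generate_phantom
from plaquemap.sensitivity import (
    CorrelationResult,
    RelocationSpec,
    correlation_sweep,
    delta_wss,
    pearson_correlation,
    project_specimen,
    relocate_and_reproject,
    wilcoxon_signed_rank,
)


def signed_rank_p_enumeration(d):
    """Exhaustive two-sided signed-rank oracle (mid-ranks), n <= 12."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absd[order[j + 1]] == absd[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = np.mean(np.arange(i + 1, j + 2))
        i = j + 1
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-12)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_identical_vectors_p_one_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero"):
            assert wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_n5_all_positive_exact(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert wilcoxon_signed_rank(a, b) == pytest.approx(0.0625, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 11)
        d = np.round(rng.normal(0, 1, n), 2)
        d = d[d != 0]
        if len(d) == 0:
            pytest.skip("all-zero draw")
        p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert p == pytest.approx(signed_rank_p_enumeration(d), abs=1e-10)

    def test_with_ties_matches_enumeration(self):
        d = np.array([0.5, 0.5, -0.5, 1.0, 1.0, 2.0])
        p = wilcoxon_signed_rank(d, np.zeros_like(d))
        assert p == pytest.approx(signed_rank_p_enumeration(d), abs=1e-10)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.3, 1.0, 60)
        from scipy.stats import wilcoxon as scipy_wilcoxon

        p = wilcoxon_signed_rank(a, np.zeros_like(a))
        ref = scipy_wilcoxon(a, correction=True).pvalue
        assert p == pytest.approx(ref, rel=0.1)

    def test_unequal_lengths(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


class TestPearson:
    def test_perfect_positive(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_correlation(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(0.0, abs=1e-12)

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_correlation(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.1, 1.9, 3.2, 3.8])
        xc, yc = x - x.mean(), y - y.mean()
        oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        res = pearson_correlation(x, y)
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_p_value_matches_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        y = 0.5 * x + rng.normal(size=12)
        from scipy.stats import pearsonr

        res = pearson_correlation(x, y)
        ref = pearsonr(x, y)
        assert res.r == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError, match="3"):
            pearson_correlation([1.0, 2.0], [1.0, 2.0])

    def test_r_bounds_enforced(self):
        with pytest.raises(ValueError):
            CorrelationResult(r=1.5, p_value=0.1, n=5)


@pytest.fixture(scope="module")
def gradient_setup():
    spec = PhantomSpec(
    n_sections=6, wss_axial_gradient_pa_per_mm=1.0, wss_baseline_pa=2.0, rng_seed=5
    )
    bundle = generate_phantom(spec)
    params = ProjectionParams()
    lumen = bundle.enface_contours.select("lumen")
    cl = compute_centerline(lumen)
    baseline = project_specimen(
    bundle.wss_surface, lumen, cl, params,
    thickness_contours=bundle.histology_contours,
    )
    return bundle, lumen, cl, params, baseline


class TestRelocation:
    def test_dz_zero_identity(self, gradient_setup):
        bundle, lumen, cl, params, baseline = gradient_setup
        out = relocate_and_reproject(
            bundle.wss_surface, lumen, cl, params, RelocationSpec(0.0),
            thickness_contours=bundle.histology_contours,
        )
        pd.testing.assert_frame_equal(out, baseline)

    def test_constant_field_unaffected(self):
        spec = PhantomSpec(n_sections=4, wss_baseline_pa=2.0, rng_seed=1)
        bundle = generate_phantom(spec)
        lumen = bundle.enface_contours.select("lumen")
        cl = compute_centerline(lumen)
        params = ProjectionParams()
        baseline = project_specimen(bundle.wss_surface, lumen, cl, params)
        out = relocate_and_reproject(
            bundle.wss_surface, lumen, cl, params, RelocationSpec(0.4)
        )
        np.testing.assert_allclose(out["mean_wss_pa"], baseline["mean_wss_pa"], atol=1e-12)

    def test_linear_field_shifts_by_minus_g_dz(self, gradient_setup):
        bundle, lumen, cl, params, baseline = gradient_setup
        out = relocate_and_reproject(
            bundle.wss_surface, lumen, cl, params, RelocationSpec(0.6),
            thickness_contours=bundle.histology_contours,
        )
        shift = out["mean_wss_pa"] - baseline["mean_wss_pa"]
        np.testing.assert_allclose(shift, -0.6, atol=1e-9)

    def test_relocate_forward_backward_restores_baseline(self, gradient_setup):
        bundle, lumen, cl, params, baseline = gradient_setup
        fwd = bundle.wss_surface.translated_z(0.3)
        restored = fwd.translated_z(-0.3)
        out = project_specimen(
            restored, lumen, cl, params, thickness_contours=bundle.histology_contours
        )
        pd.testing.assert_frame_equal(out, baseline)


class TestDeltaWss:
    def test_zero_when_identical(self, gradient_setup):
        _, _, _, _, baseline = gradient_setup
        deltas = delta_wss(baseline, baseline)
        assert (deltas["grand"].iloc[0] == 0.0).all()

    def test_linear_gradient_grand_average(self, gradient_setup):
        bundle, lumen, cl, params, baseline = gradient_setup
        out = relocate_and_reproject(
            bundle.wss_surface, lumen, cl, params, RelocationSpec(0.6),
            thickness_contours=bundle.histology_contours,
        )
        grand = delta_wss(baseline, out)["grand"].iloc[0]
        assert grand["abs_delta_mean_wss_pa"] == pytest.approx(0.6, rel=1e-9)

    def test_monotone_in_dz_binwise(self, gradient_setup):
        bundle, lumen, cl, params, baseline = gradient_setup
        d3 = delta_wss(
            baseline,
            relocate_and_reproject(
                bundle.wss_surface, lumen, cl, params, RelocationSpec(0.3),
                thickness_contours=bundle.histology_contours,
            ),
        )["per_bin"]
        d6 = delta_wss(
            baseline,
            relocate_and_reproject(
                bundle.wss_surface, lumen, cl, params, RelocationSpec(0.6),
                thickness_contours=bundle.histology_contours,
            ),
        )["per_bin"]
        assert (
            d6["abs_delta_mean_wss_pa"].to_numpy()
            >= d3["abs_delta_mean_wss_pa"].to_numpy() - 1e-12
        ).all()

    def test_key_mismatch_rejected(self, gradient_setup):
        _, _, _, _, baseline = gradient_setup
        other = baseline.copy()
        other["slice_index"] = other["slice_index"] + 100
        with pytest.raises(ValueError, match="mismatch"):
            delta_wss(baseline, other)


@pytest.fixture(scope="module")
def anti_setup():
    # thickness constructed anti-proportional to the circumferential WSS
    spec = PhantomSpec(
        n_sections=5,
        wss_circumferential_amplitude_pa=1.0,
        wss_axial_gradient_pa_per_mm=0.2,
        wss_baseline_pa=2.0,
        thickness_circ_amplitude_mm=0.5,
        rng_seed=9,
    )
    bundle = generate_phantom(spec)
    lumen = bundle.enface_contours.select("lumen")
    cl = compute_centerline(lumen)
    params = ProjectionParams()
    tables = {
        dz: relocate_and_reproject(
            bundle.wss_surface, lumen, cl, params, RelocationSpec(dz),
            thickness_contours=bundle.histology_contours,
        )
        for dz in (-0.3, 0.0, 0.3)
    }
    return tables


class TestCorrelationSweep:
    def test_all_relocations_identical_gives_zero_delta_r(self, anti_setup):
        table = anti_setup[0.0]
        out = correlation_sweep({0.0: table, 0.3: table.copy()})
        assert len(out) > 0
        assert np.allclose(out["delta_r"], 0.0)

    def test_anti_proportional_thickness_negative_everywhere(self, anti_setup):
        out = correlation_sweep(anti_setup, "mean")
        assert len(out) > 0
        assert (out["r"] < 0).all()
        assert (out["p_value"] < 0.05).all()
        assert out["significant"].all()

    def test_significance_retained_across_sweep(self, anti_setup):
        out = correlation_sweep(anti_setup, "mean")
        for dz in (-0.3, 0.3):
            sub = out[out["dz_mm"] == dz]
            assert sub["significant"].all()

    def test_too_few_bins_skipped(self, anti_setup):
        table = anti_setup[0.0].copy()
        table.loc[table["slice_index"] == 0, "included"] = False
        two_left = table[
            (table["slice_index"] == 1) & (table["bin_index"] >= 2)
        ].index
        table.loc[two_left, "included"] = False
        out = correlation_sweep({0.0: table})
        assert 0 not in out["slice_index"].to_numpy()
        assert 1 not in out["slice_index"].to_numpy()

    def test_baseline_required(self, anti_setup):
        with pytest.raises(ValueError, match="baseline"):
            correlation_sweep({0.3: anti_setup[0.3]})
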