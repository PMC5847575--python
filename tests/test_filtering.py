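"""Q-value filter policies and robust-sum normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from diaq import QValueFilter, RobustSumNormalizer, filter_audit
from diaq.filtering import FILTER_MODES, robust_sum_normalize
from diaq.io import ConfigurationError, InputError, QuantMatrix


@pytest.fixture
def spec_toy_qvalues() -> pd.DataFrame:
    """3 precursors × 4 runs with graded identification confidence."""
    return pd.DataFrame(
        {
            "P1": [0.001, 0.001, 0.001, 0.001],
            "P2": [0.001, 0.001, 0.5, 0.5],
            "P3": [0.5, 0.5, 0.5, 0.001],
        },
        index=[f"r{i}" for i in range(4)],
    )


def kept(mode, q, **kw):
    f = QValueFilter(mode=mode, **kw).fit(q)
    return set(f.kept_precursors_)


class TestPolicies:
    def test_hand_enumerated_toy_table(self, spec_toy_qvalues):
        q = spec_toy_qvalues
        assert kept("complete", q) == {"P1"}
        assert kept("median", q) == {"P1", "P2"}
        assert kept("percentile", q, percentile_fraction=0.1) == {"P1", "P2", "P3"}
        assert kept("sparse", q) == {"P1", "P2", "P3"}

    def test_all_passing_keeps_everything_under_every_mode(self):
        q = pd.DataFrame(np.full((5, 4), 0.001),
                         columns=list("abcd"))
        for mode in FILTER_MODES:
            assert kept(mode, q) == set("abcd")

    def test_vacuous_cutoff_keeps_everything(self, spec_toy_qvalues):
        for mode in FILTER_MODES:
            assert kept(mode, spec_toy_qvalues, qvalue_cutoff=1.0) == \
                {"P1", "P2", "P3"}

    def test_missing_qvalue_counts_as_failing(self):
        q = pd.DataFrame({"a": [0.001, np.nan]}, index=["r1", "r2"])
        assert kept("complete", q) == set()
        assert kept("sparse", q) == {"a"}

    def test_unknown_mode_is_configuration_error(self):
        with pytest.raises(ConfigurationError, match="mode"):
            QValueFilter(mode="bogus").fit(pd.DataFrame({"a": [0.1]}))

    def test_transform_keeps_all_runs_of_kept_precursors(self, spec_toy_qvalues):
        intens = pd.DataFrame(np.arange(12.0).reshape(4, 3),
                              index=spec_toy_qvalues.index,
                              columns=spec_toy_qvalues.columns)
        f = QValueFilter("median").fit(spec_toy_qvalues)
        out = f.transform(intens)
        # precursor-level filtering: high-q cells of kept precursors survive
        assert list(out.columns) == ["P1", "P2"]
        assert out.notna().all().all()

    @settings(max_examples=50, deadline=None)
    @given(q=arrays(float, (7, 12), elements=st.floats(0.0, 1.0)),
           p=st.floats(0.05, 0.5))
    def test_policy_nesting_on_random_matrices(self, q, p):
        qdf = pd.DataFrame(q, columns=[f"c{i}" for i in range(12)])
        s_complete = kept("complete", qdf)
        s_median = kept("median", qdf)
        s_pct = kept("percentile", qdf, percentile_fraction=p)
        s_sparse = kept("sparse", qdf)
        assert s_complete <= s_median <= s_pct <= s_sparse

    @settings(max_examples=30, deadline=None)
    @given(q=arrays(float, (6, 10), elements=st.floats(0.0, 1.0)))
    def test_kept_set_shrinks_with_stricter_cutoff_and_fraction(self, q):
        qdf = pd.DataFrame(q, columns=[f"c{i}" for i in range(10)])
        for mode in FILTER_MODES:
            strict = kept(mode, qdf, qvalue_cutoff=0.005)
            loose = kept(mode, qdf, qvalue_cutoff=0.05)
            assert strict <= loose
        assert kept("percentile", qdf, percentile_fraction=0.4) <= \
            kept("percentile", qdf, percentile_fraction=0.2)

    def test_audit_reports_all_modes(self, spec_toy_qvalues):
        audit = filter_audit(spec_toy_qvalues)
        assert list(audit.columns) == list(FILTER_MODES)
        assert audit.loc["P2", "median"]
        assert not audit.loc["P2", "complete"]


def random_linear_matrix(seed: int, n_runs=6, n_prec=30) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    return pd.DataFrame(rng.lognormal(8, 1.5, (n_runs, n_prec)),
                        index=[f"r{i}" for i in range(n_runs)],
                        columns=[f"p{i:02d}" for i in range(n_prec)])


class TestRobustSum:
    def test_identical_runs_get_unit_factors(self):
        row = np.linspace(10, 200, 20)
        V = pd.DataFrame([row, row], index=["a", "b"],
                         columns=[f"p{i:02d}" for i in range(20)])
        out, norm = robust_sum_normalize(V)
        np.testing.assert_allclose(norm.factors_, 1.0)
        pd.testing.assert_frame_equal(out, V)

    def test_doubled_run_is_rescaled_to_common_sums(self):
        row = np.linspace(10, 200, 20)
        V = pd.DataFrame([row, 2 * row], index=["A", "B"],
                         columns=[f"p{i:02d}" for i in range(20)])
        out, norm = robust_sum_normalize(V)
        # hand computation: S_B = 2 S_A, target = median = 1.5 S_A
        s_a = row[2:18].sum()
        assert norm.target_sum_ == pytest.approx(1.5 * s_a)
        assert norm.factors_["A"] == pytest.approx(1.5)
        assert norm.factors_["B"] == pytest.approx(0.75)
        pd.testing.assert_frame_equal(out.loc[["A"]].set_axis(["B"]),
                                      out.loc[["B"]])
        sums = out[list(norm.pool_)].sum(axis=1)
        assert np.allclose(sums / sums.iloc[0], 1.0, rtol=1e-9)

    def test_pool_boundaries_floor_of_fraction(self):
        V = random_linear_matrix(0, n_prec=10)
        norm = RobustSumNormalizer(0.10).fit(V)
        assert len(norm.pool_) == 8

    def test_idempotent_on_random_fixtures(self):
        for seed in range(5):
            V = random_linear_matrix(seed)
            once, _ = robust_sum_normalize(V)
            twice, norm2 = robust_sum_normalize(once)
            np.testing.assert_allclose(twice.to_numpy(), once.to_numpy(),
                                       rtol=1e-9)
            np.testing.assert_allclose(norm2.factors_, 1.0, rtol=1e-9)

    def test_equivariant_to_per_run_rescaling(self):
        # relative profiles are exactly invariant; the common level is exactly
        # invariant when the rescaled run does not alter the median pool sum
        V = random_linear_matrix(3)
        out1, norm1 = robust_sum_normalize(V)
        top = norm1.robust_sums_.idxmax()
        V2 = V.copy()
        V2.loc[top] *= 7.5                      # stays the largest sum
        out2, _ = robust_sum_normalize(V2)
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(), rtol=1e-9)

    def test_relative_profiles_invariant_to_any_run_rescaling(self):
        V = random_linear_matrix(3)
        out1, _ = robust_sum_normalize(V)
        V2 = V.copy()
        V2.iloc[2] *= 7.5
        out2, _ = robust_sum_normalize(V2)
        ratio = out2.to_numpy() / out1.to_numpy()
        np.testing.assert_allclose(ratio, ratio.flat[0], rtol=1e-9)

    def test_normalized_robust_sums_agree(self):
        V = random_linear_matrix(4)
        out, norm = robust_sum_normalize(V)
        sums = out[list(norm.pool_)].sum(axis=1)
        assert np.allclose(sums, norm.target_sum_, rtol=1e-9)

    def test_pool_excludes_incomplete_precursors(self):
        V = random_linear_matrix(5)
        V.iloc[0, 5] = np.nan
        norm = RobustSumNormalizer(0.10).fit(V)
        assert "p05" not in norm.pool_

    def test_empty_pool_raises_helpful_error(self):
        # every precursor misses one run: no complete pool member remains
        V = random_linear_matrix(6, n_prec=12)
        for j in range(12):
            V.iloc[j % V.shape[0], j] = np.nan
        with pytest.raises(InputError, match="pool"):
            RobustSumNormalizer(0.10).fit(V)

    def test_rejects_log2_scale_matrix(self):
        mat = QuantMatrix(random_linear_matrix(8), "log2")
        with pytest.raises(ConfigurationError, match="linear"):
            RobustSumNormalizer().fit(mat)
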