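"""PGS arithmetic and invariances, case/control assembly rules, logistic
fits against an independently coded IRLS oracle, and BH behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

from virtmet.dataio import GenotypePanel, PhecodeMap, ScoreEntry, ScoreModel, VariantKey
from virtmet.scores import (CaseControlSet, InstrumentError, assemble_case_control,
                            bh_adjust, compute_pgs, fit_logistic, linear_gwas,
                            phewas_scan, snp_outcome_gwas)


def _panel(dosages, missing=None, mafs=None):
    dosages = np.asarray(dosages, float)
    m = dosages.shape[1]
    variants = pd.DataFrame({
        "variant": [f"rs{j + 1}" for j in range(m)],
        "chrom": [str(j + 1) for j in range(m)],
        "pos": [100 * (j + 1) for j in range(m)],
        "ref": ["A"] * m, "alt": ["G"] * m,
        "eaf": mafs if mafs is not None else dosages.mean(axis=0) / 2,
    })
    ids = [f"s{i}" for i in range(dosages.shape[0])]
    return GenotypePanel(ids, variants, dosages,
                         np.asarray(missing, bool) if missing is not None else None)


def _model(weights, effect_alleles=None, mid="m"):
    effect_alleles = effect_alleles or ["G"] * len(weights)
    entries = [
        ScoreEntry(VariantKey(str(j + 1), 100 * (j + 1), "A", "G", f"rs{j + 1}"),
                   ea, w)
        for j, (ea, w) in enumerate(zip(effect_alleles, weights))
    ]
    return ScoreModel(mid, entries)


def _irls_logistic(y, X, n_iter=60):
    """Independent iteratively-reweighted least-squares oracle."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
        WX = X * W[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (W * z))
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    cov = np.linalg.inv(X.T @ (X * (expit(X @ beta) * (1 - expit(X @ beta)))[:, None]))
    return beta, np.sqrt(np.diag(cov))


class TestComputePgs:
    def test_weighted_sum_arithmetic(self):
        panel = _panel([[0, 1, 2]])
        pgs = compute_pgs(panel, _model([0.5, 1.0, -0.2]))
        assert pgs.values[0] == pytest.approx(0.6)
        assert pgs.n_variants_used == 3

    def test_ref_effect_allele_counts_other_dosage(self):
        panel = _panel([[0.0], [2.0]])
        pgs = compute_pgs(panel, _model([1.0], effect_alleles=["A"]))
        assert list(pgs.values) == [2.0, 0.0]

    def test_mean_impute_uses_twice_eaf(self):
        panel = _panel([[0], [1], [2], [1]], missing=[[1], [0], [0], [0]])
        pgs = compute_pgs(panel, _model([1.0]), missing_policy="mean_impute")
        eaf = np.mean([1, 2, 1]) / 2.0
        assert pgs.values[0] == pytest.approx(2 * eaf)
        assert pgs.n_missing_handled == 1

    def test_drop_variant_policy_removes_variant(self):
        panel = _panel([[0, 1], [1, 2]], missing=[[1, 0], [0, 0]])
        pgs = compute_pgs(panel, _model([1.0, 1.0]), missing_policy="drop_variant")
        assert pgs.n_variants_used == 1
        assert list(pgs.values) == [1.0, 2.0]

    def test_no_overlap_raises_instrument_error(self):
        panel = _panel([[0, 1]])
        model = ScoreModel("m", [ScoreEntry(VariantKey("9", 999, "A", "G"), "G", 1.0)])
        with pytest.raises(InstrumentError, match="9:999"):
            compute_pgs(panel, model)

    def test_zero_weights_cannot_be_standardized(self):
        panel = _panel([[0, 1], [2, 1]])
        pgs = compute_pgs(panel, _model([0.0, 0.0]))
        with pytest.raises(ValueError, match="constant score"):
            pgs.standardized()

    def test_allele_relabel_invariance_of_association(self):
        rng = np.random.default_rng(5)
        dosages = rng.integers(0, 3, size=(3000, 3)).astype(float)
        panel = _panel(dosages)
        model_a = _model([0.5, 1.0, -0.2])
        # flip entry 1 to the other allele and negate its weight
        model_b = _model([0.5, -1.0, -0.2], effect_alleles=["G", "A", "G"])
        pgs_a, pgs_b = compute_pgs(panel, model_a), compute_pgs(panel, model_b)
        shift = pgs_a.values - pgs_b.values
        assert np.allclose(shift, shift[0])
        lin = 0.4 * pgs_a.standardized()
        y = (rng.uniform(size=3000) < expit(-1 + lin)).astype(float)
        fa = fit_logistic(y, pgs_a.standardized())
        fb = fit_logistic(y, pgs_b.standardized())
        assert abs(fa.beta - fb.beta) < 1e-10


class TestCaseControl:
    def _inputs(self):
        events = pd.DataFrame({
            "individual_id": ["case1", "case1", "one_hit", "old_ctrl_rel"],
            "phecode": ["574.1", "574.1", "574.1", "574.2"],
            "count": [1, 1, 1, 1],
        })
        cov = pd.DataFrame(
            {"age": [50.0, 50.0, 50.0, 50.0, 95.0]},
            index=pd.Index(["case1", "one_hit", "old_ctrl_rel", "ctrl", "too_old"],
                           name="individual_id"))
        m = PhecodeMap("574.1", [(574.0, 574.99)], min_cases=1)
        return events, m, cov

    def test_partition_rules(self):
        events, m, cov = self._inputs()
        cc = assemble_case_control(events, m, cov)
        assert cc.case_ids == ["case1"]            # two instances
        assert "one_hit" in cc.excluded_ids        # in range, not a case
        assert "old_ctrl_rel" in cc.excluded_ids   # related code
        assert "too_old" in cc.excluded_ids        # outside case age window
        assert cc.control_ids == ["ctrl"]
        assert set(cc.case_ids) | set(cc.control_ids) | set(cc.excluded_ids) == set(cov.index)

    def test_age_window_is_case_range(self):
        events, m, cov = self._inputs()
        cc = assemble_case_control(events, m, cov)
        assert cc.age_window == (50.0, 50.0)

    def test_empty_case_set_unanalyzable(self):
        events, m, cov = self._inputs()
        cc = assemble_case_control(events[events.individual_id == "none"], m, cov)
        assert not cc.analyzable and cc.n_cases == 0


class TestFitLogistic:
    def test_constant_exposure_rank_error(self):
        y = np.array([0, 1] * 50)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_logistic(y, np.ones(100))

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(np.zeros(50), np.random.default_rng(0).normal(size=50))

    def test_recovers_known_log_odds_ratio(self):
        rng = np.random.default_rng(42)
        n = 20_000
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < expit(-2 + 0.3 * x)).astype(float)
        fit = fit_logistic(y, x)
        assert abs(fit.beta - 0.3) < 3 * fit.se

    def test_matches_irls_oracle_on_random_datasets(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(200, 500))
            x = rng.normal(size=n)
            c = rng.normal(size=(n, 2))
            y = (rng.uniform(size=n) < expit(0.2 + 0.5 * x + 0.3 * c[:, 0])).astype(float)
            fit = fit_logistic(y, x, c)
            X = np.column_stack([np.ones(n), x, c])
            beta_o, se_o = _irls_logistic(y, X)
            assert abs(fit.beta - beta_o[1]) < 1e-6
            assert abs(fit.se - se_o[1]) < 1e-6


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.03]))[0] == pytest.approx(0.03)

    def test_step_up_example(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, 0.04)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30),
           st.randoms(use_true_random=False))
    def test_monotone_deterministic_permutation_equivariant(self, ps, rnd):
        p = np.array(ps)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.array_equal(q, bh_adjust(p))
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        assert np.allclose(bh_adjust(p[perm]), q[perm])


class TestScans:
    def test_phewas_single_cell_q_equals_p(self):
        rng = np.random.default_rng(1)
        dosages = rng.integers(0, 3, size=(800, 2)).astype(float)
        panel = _panel(dosages)
        pgs = compute_pgs(panel, _model([0.5, 0.3]))
        y = rng.integers(0, 2, 800)
        ids = np.array(panel.sample_ids)
        cov = pd.DataFrame({"age": rng.uniform(20, 80, 800),
                            "sex": rng.integers(0, 2, 800).astype(float)},
                           index=pd.Index(ids, name="individual_id"))
        cc = CaseControlSet("574.1", list(ids[y == 1]), list(ids[y == 0]), [],
                            (20, 80))
        out = phewas_scan([pgs], {"574.1": cc}, cov)
        assert len(out) == 1
        assert out["q"].iloc[0] == pytest.approx(out["p"].iloc[0])

    def test_snp_gwas_monomorphic_flagged_and_effect_recovered(self):
        rng = np.random.default_rng(2)
        n = 20_000
        d = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        d[:, 1] = 0.0  # monomorphic
        panel = _panel(d)
        y = (rng.uniform(size=n) < expit(-2 + 0.4 * (d[:, 0] - d[:, 0].mean()))).astype(float)
        cov = pd.DataFrame(
            {"age": rng.uniform(20, 80, n), "sex": rng.integers(0, 2, n).astype(float),
             **{f"PC{k+1}": rng.normal(size=n) for k in range(10)}},
            index=pd.Index(panel.sample_ids, name="individual_id"))
        out = snp_outcome_gwas(panel, y, cov)
        assert ("rs2", "monomorphic") in out.attrs["flagged"]
        row = out[out.variant == "rs1"].iloc[0]
        assert abs(row.beta - 0.4) < 3 * row.se

    def test_linear_gwas_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.4, size=(500, 4)).astype(float)
        panel = _panel(d)
        y = 0.3 * d[:, 2] + rng.normal(size=500)
        out = linear_gwas(panel, y)
        for j, row in out.iterrows():
            fit = sm.OLS(y, sm.add_constant(d[:, j])).fit()
            assert row.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert row.se == pytest.approx(fit.bse[1], rel=1e-10)
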