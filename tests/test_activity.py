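"""Replicate-noise model, differential activity, correction, projection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, lognorm

from imodkit.activity import (
    ActivityError,
    ActivityTable,
    activity_expression_association,
    correct_profile,
    fit_replicate_noise,
    project_onto_basis,
)
from imodkit.activity import test_differential_activity as run_differential_activity
from imodkit.thresholding import IModulon


def lognormal_replicate_table(rng, n_imodulons=1, n_groups=200, mu=0.0, sigma=0.5):
    """Activity table whose within-group replicate differences are exact
    log-normal draws: each group holds samples at (0, d)."""
    samples = []
    groups = {}
    data = {f"im{i}": [] for i in range(n_imodulons)}
    for g in range(n_groups):
        for r, offset in enumerate(("a", "b")):
            s = f"grp{g}_{offset}"
            samples.append(s)
            groups[s] = f"grp{g}"
    for i in range(n_imodulons):
        row = []
        for g in range(n_groups):
            d = lognorm.rvs(s=sigma, scale=np.exp(mu), random_state=rng)
            row += [0.0, d]
        data[f"im{i}"] = row
    A = pd.DataFrame(data, index=samples).T
    cond = pd.Series({s: groups[s] for s in samples})
    return ActivityTable(A, cond, pd.Series(groups))


class TestNoiseModel:
    def test_lognormal_parameters_recovered(self):
        rng = np.random.default_rng(0)
        table = lognormal_replicate_table(rng, n_groups=200, mu=0.0, sigma=0.5)
        model = fit_replicate_noise(table)
        assert abs(model.params.loc["im0", "mu"] - 0.0) < 0.1
        assert abs(model.params.loc["im0", "sigma"] - 0.5) < 0.1

    def test_identical_replicates_flagged_degenerate(self):
        A = pd.DataFrame(
            {"s1": [1.0], "s2": [1.0], "s3": [2.0], "s4": [2.0]}, index=["im0"]
        )
        groups = pd.Series({"s1": "a", "s2": "a", "s3": "b", "s4": "b"})
        table = ActivityTable(A, groups, groups)
        model = fit_replicate_noise(table)
        assert model.is_degenerate("im0")

    def test_ks_goodness_of_fit_calibrated(self):
        passing = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            table = lognormal_replicate_table(rng, n_groups=100)
            model = fit_replicate_noise(table)
            if model.params.loc["im0", "ks_p"] > 0.05:
                passing += 1
        assert passing >= 90


class TestDifferentialActivity:
    def build_table(self, rng, shift=0.0, sigma=0.5):
        """Two test conditions (2 reps each) plus noise-fitting groups."""
        table = lognormal_replicate_table(rng, n_groups=50, sigma=sigma)
        A = table.A.copy()
        for cond, level in (("c1", 0.0), ("c2", shift)):
            for r in range(2):
                A[f"{cond}_r{r}"] = level + rng.normal(0, 0.1)
        cond = dict(table.condition_map)
        groups = dict(table.replicate_groups)
        for cnd in ("c1", "c2"):
            for r in range(2):
                cond[f"{cnd}_r{r}"] = cnd
                groups[f"{cnd}_r{r}"] = cnd
        return ActivityTable(A, pd.Series(cond), pd.Series(groups))

    def test_condition_against_itself_is_null(self):
        rng = np.random.default_rng(1)
        table = self.build_table(rng)
        noise = fit_replicate_noise(table)
        out = run_differential_activity(table, noise, "c1", "c1")
        assert (out["delta_A"] == 0).all()
        assert not out["significant"].any()

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(2)
        table = self.build_table(rng, shift=20.0)
        noise = fit_replicate_noise(table)
        out = run_differential_activity(table, noise, "c1", "c2")
        row = out.set_index("imodulon").loc["im0"]
        assert row["delta_A"] == pytest.approx(20.0, abs=1.0)
        # closed-form tail of the fitted log-normal is tiny at |dA| = 20
        assert row["pvalue"] < 1e-6
        assert bool(row["significant"])

    def test_pvalues_uniform_under_null(self):
        # both conditions drawn from the replicate-noise model itself
        rng = np.random.default_rng(3)
        table = lognormal_replicate_table(rng, n_groups=100, sigma=0.5)
        model = fit_replicate_noise(table)
        sigma, mu = model.params.loc["im0", ["sigma", "mu"]]
        pvals = []
        for _ in range(400):
            d = lognorm.rvs(s=0.5, scale=1.0, random_state=rng)
            pvals.append(float(lognorm.sf(d, s=sigma, scale=np.exp(mu))))
        ks = kstest(pvals, "uniform").statistic
        assert ks < 0.1

    def test_degenerate_imodulon_skipped(self):
        rng = np.random.default_rng(4)
        cols = {}
        groups = {}
        for g in range(6):
            d = float(lognorm.rvs(s=0.5, random_state=rng))
            cols[f"grp{g}_a"] = [float(g), 0.0]
            cols[f"grp{g}_b"] = [float(g), d]
            groups[f"grp{g}_a"] = groups[f"grp{g}_b"] = f"grp{g}"
        A = pd.DataFrame(cols, index=["flat", "ok"])
        groups = pd.Series(groups)
        table = ActivityTable(A, groups, groups)
        model = fit_replicate_noise(table)
        assert model.is_degenerate("flat") and not model.is_degenerate("ok")
        out = run_differential_activity(table, model, "grp0", "grp1")
        assert list(out["imodulon"]) == ["ok"]


def toy_basis(rng, n_genes=60, n_components=3):
    genes = [f"g{i}" for i in range(n_genes)]
    S = pd.DataFrame(
        rng.normal(size=(n_genes, n_components)),
        index=genes,
        columns=[f"M{k}" for k in range(n_components)],
    )
    return S / np.linalg.norm(S, axis=0)


class TestCorrectProfile:
    def make_imodulon(self, S, col, n_sig=8):
        weights = S[col].abs().nlargest(n_sig)
        return IModulon(
            name=col,
            component_index=list(S.columns).index(col),
            gene_weights=S[col][weights.index].abs(),  # positive: orientation holds
            threshold_stat=550.0,
        )

    def test_constructed_shift_inverted_exactly(self, rng):
        S = toy_basis(rng).abs()
        im = self.make_imodulon(S, "M0")
        x1 = pd.Series(rng.normal(size=len(S)), index=S.index)
        s_tilde = pd.Series(0.0, index=S.index)
        s_tilde[list(im.gene_weights.index)] = S.loc[list(im.gene_weights.index), "M0"]
        delta = 7.5
        x2 = x1 + s_tilde * delta
        a_ref = {"M0": 0.0}
        a_target = {"M0": delta}
        corrected = correct_profile(x2, [im], S, a_target, a_ref)
        assert np.allclose(corrected, x1, atol=1e-12)

    def test_empty_selection_is_identity(self, rng):
        S = toy_basis(rng)
        x2 = pd.Series(rng.normal(size=len(S)), index=S.index)
        out = correct_profile(x2, [], S, {}, {})
        assert (out == x2).all()

    def test_negated_delta_restores_original(self, rng):
        S = toy_basis(rng).abs()
        im = self.make_imodulon(S, "M1")
        x2 = pd.Series(rng.normal(size=len(S)), index=S.index)
        fwd = correct_profile(x2, [im], S, {"M1": 4.0}, {"M1": 1.0})
        back = correct_profile(fwd, [im], S, {"M1": 1.0}, {"M1": 4.0})
        assert np.allclose(back, x2, atol=1e-12)

    def test_two_strain_fixture_r2_recovers(self, rng):
        # strain B = strain A + two planted i-modulon effects + noise
        S = toy_basis(rng, n_genes=300).abs()
        ims = [self.make_imodulon(S, "M0", 20), self.make_imodulon(S, "M1", 20)]
        affected = sorted(set(ims[0].gene_weights.index) | set(ims[1].gene_weights.index))
        xA = pd.Series(rng.normal(size=300), index=S.index)
        effect = pd.Series(0.0, index=S.index)
        for im, col, delta in zip(ims, ["M0", "M1"], [12.0, -9.0]):
            s_tilde = pd.Series(0.0, index=S.index)
            s_tilde[list(im.gene_weights.index)] = S.loc[list(im.gene_weights.index), col]
            effect += s_tilde * delta
        xB = xA + effect + rng.normal(0, 0.05, 300)
        before = np.corrcoef(xA[affected], xB[affected])[0, 1] ** 2
        corrected = correct_profile(
            xB, ims, S, {"M0": 12.0, "M1": -9.0}, {"M0": 0.0, "M1": 0.0}
        )
        after = np.corrcoef(xA[affected], corrected[affected])[0, 1] ** 2
        assert before < 0.5 < 0.95 < after

    def test_mismatched_gene_index_rejected(self, rng):
        S = toy_basis(rng)
        x2 = pd.Series(rng.normal(size=5), index=[f"other{i}" for i in range(5)])
        with pytest.raises(ActivityError):
            correct_profile(x2, [], S, {}, {})


class TestProjection:
    def test_exact_recovery_for_full_rank_basis(self, rng):
        S = toy_basis(rng)
        a = pd.DataFrame({"new": [2.0, -1.0, 0.5]}, index=S.columns)
        X_new = S @ a
        out = project_onto_basis(S, X_new)
        assert np.allclose(out, a, atol=1e-10)

    def test_zero_profiles_give_zero_activities(self, rng):
        S = toy_basis(rng)
        X_new = pd.DataFrame(0.0, index=S.index, columns=["z"])
        assert np.allclose(project_onto_basis(S, X_new), 0.0)

    def test_residual_orthogonal_to_basis(self, rng):
        S = toy_basis(rng)
        X_new = pd.DataFrame(rng.normal(size=(len(S), 2)), index=S.index)
        A_new = project_onto_basis(S, X_new)
        residual = X_new.to_numpy() - S.to_numpy() @ A_new.to_numpy()
        assert np.max(np.abs(S.to_numpy().T @ residual)) < 1e-8

    def test_shared_gene_restriction_recorded(self, rng):
        S = toy_basis(rng)
        X_new = pd.DataFrame(
            rng.normal(size=(30, 1)), index=list(S.index[:30]), columns=["x"]
        )
        out = project_onto_basis(S, X_new)
        assert out.attrs["shared_genes"] == list(S.index[:30])

    def test_training_activities_reproduced(self, small_world, small_decomposition):
        centered, _, _ = small_world
        dec = small_decomposition
        A_hat = project_onto_basis(dec.S, centered.values)
        for comp in dec.A.index:
            r2 = np.corrcoef(A_hat.loc[comp], dec.A.loc[comp])[0, 1] ** 2
            assert r2 >= 0.99


class TestAssociation:
    def test_exact_linear_relation(self, rng):
        x = pd.Series(rng.normal(size=50), index=[f"s{i}" for i in range(50)])
        y = 3 * x + 2
        rec = activity_expression_association(y, x)
        assert rec.r2 == pytest.approx(1.0)
        assert rec.slope == pytest.approx(3.0)

    def test_independent_rows_have_no_association(self):
        high = 0
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            idx = [f"s{i}" for i in range(200)]
            act = pd.Series(rng.normal(size=200), index=idx)
            expr = pd.Series(rng.normal(size=200), index=idx)
            if activity_expression_association(act, expr).r2 >= 0.05:
                high += 1
        assert high <= 5

    def test_breakpoint_pattern_prefers_piecewise_fit(self, rng):
        idx = [f"s{i}" for i in range(100)]
        x = pd.Series(np.linspace(0, 10, 100), index=idx)
        y = np.where(x < 5, 0.0, 4.0 * (x - 5)) + rng.normal(0, 0.2, 100)
        rec = activity_expression_association(pd.Series(y, index=idx), x)
        assert rec.piecewise_adj_r2 > rec.adj_r2
        assert rec.breakpoint == pytest.approx(5.0, abs=0.5)

    def test_exclusion_below_three_samples_rejected(self, rng):
        idx = ["a", "b", "c"]
        act = pd.Series(rng.normal(size=3), index=idx)
        with pytest.raises(ActivityError):
            activity_expression_association(act, act, exclude_samples=["a"])
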