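import numpy as np
import pandas as pd
import pytest

from nabsel.model import (
    AnimalModel,
    SingularDesignError,
    build_fixed_design,
    genetic_trend,
    lrt,
    ratios,
)
from nabsel.pedigree import build_pedigree, relationship_matrix
from nabsel.simulate import LocusSpec, default_config, run_experiment

from conftest import random_pedigree


def half_sib_data(n_sires=100, k=20, s2a=0.8, s2e=0.6, seed=1):
    rng = np.random.default_rng(seed)
    recs, rows = [], []
    for i in range(n_sires):
        s = f"S{i}"
        recs.append({"animal": s, "sire": "0", "dam": "0"})
        a_s = rng.normal(0, np.sqrt(s2a))
        for j in range(k):
            an = f"P{i}_{j}"
            recs.append({"animal": an, "sire": s, "dam": "0"})
            a = 0.5 * a_s + rng.normal(0, np.sqrt(0.75 * s2a))
            rows.append({"animal": an, "sire_grp": i,
                         "y": 5 + a + rng.normal(0, np.sqrt(s2e))})
    return build_pedigree(pd.DataFrame(recs)), pd.DataFrame(rows)


class TestDesign:
    def test_interaction_block_and_slices(self):
        df = pd.DataFrame({"g": ["GG", "CG/CC"] * 4, "sex": list("MFMFMMFF")})
        X, names, sl = build_fixed_design(df, ("g", "sex", "g:sex"))
        assert names == ["intercept", "g[CG/CC]", "sex[M]", "g[CG/CC]:sex[M]"]
        inter = X[:, sl["g:sex"]].ravel()
        np.testing.assert_allclose(inter, X[:, 1] * X[:, 2])

    def test_generation_aliased_with_plate_raises(self):
        rng = np.random.default_rng(0)
        n = 120
        gen = np.repeat([0, 1, 2], n // 3)
        plate = [f"G{g}P{i % 2}" for i, g in enumerate(gen)]  # plates nested in generation
        df = pd.DataFrame({"plate": plate, "generation": gen.astype(str)})
        with pytest.raises(SingularDesignError, match="aliased"):
            build_fixed_design(df, ("plate", "generation"))

    def test_genotype_levels_use_gg_baseline(self):
        df = pd.DataFrame({"genotype": ["CC", "GG", "CG", "GG"]})
        _, names, _ = build_fixed_design(df, ("genotype",))
        assert names == ["intercept", "genotype[CG]", "genotype[CC]"]


class TestRemlOracles:
    def test_balanced_half_sib_equals_anova(self):
        """REML on a balanced paternal half-sib design reproduces the
        closed-form ANOVA sire-variance estimator."""
        ped, df = half_sib_data()
        res = AnimalModel(df, ped, "y", fixed=(), maternal_env=False).fit(se=False)
        g = df.groupby("sire_grp")["y"]
        k = 20
        means, grand = g.mean(), df["y"].mean()
        msb = k * ((means - grand) ** 2).sum() / (len(means) - 1)
        msw = ((df["y"] - means[df["sire_grp"]].to_numpy()) ** 2).sum() / (
            len(df) - len(means)
        )
        anova_sire = (msb - msw) / k
        assert res.components["sigma2_A"] / 4 == pytest.approx(anova_sire, abs=1e-4)

    def test_loglike_matches_dense_gls_formula(self, small_recovery_sim):
        """Engine llf equals the textbook restricted likelihood computed densely."""
        sim = small_recovery_sim
        df = sim.phenotypes.iloc[:250].reset_index(drop=True)
        ped = sim.pedigree.prune(df["animal"])
        A = relationship_matrix(ped).a_matrix
        comp = {"sigma2_A": 0.3, "sigma2_m": 0.06, "sigma2_e": 0.9}
        m = AnimalModel(df, ped, "IgM")
        X = m.X
        n = len(df)
        ai = ped.indices(df["animal"])
        Za = np.zeros((n, ped.n))
        Za[np.arange(n), ai] = 1
        codes, _ = pd.factorize(df["dam_group"].astype(str), sort=True)
        Zm = np.zeros((n, codes.max() + 1))
        Zm[np.arange(n), codes] = 1
        V = (comp["sigma2_A"] * Za @ A @ Za.T + comp["sigma2_m"] * Zm @ Zm.T
             + comp["sigma2_e"] * np.eye(n))
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
        y = df["IgM"].to_numpy()
        p = X.shape[1]
        dense = -0.5 * (
            (n - p) * np.log(2 * np.pi)
            + np.linalg.slogdet(V)[1]
            + np.linalg.slogdet(XtViX)[1]
            - np.linalg.slogdet(X.T @ X)[1]
            + y @ P @ y
        )
        assert m.loglike(comp) == pytest.approx(dense, abs=1e-6)

    def test_llf_invariant_to_fixed_effect_coding(self, small_recovery_sim):
        sim = small_recovery_sim
        df = sim.phenotypes.iloc[:400].reset_index(drop=True)
        ped = sim.pedigree.prune(df["animal"])
        comp = {"sigma2_A": 0.35, "sigma2_m": 0.04, "sigma2_e": 0.8}
        l1 = AnimalModel(df, ped, "IgM", coding="treatment").loglike(comp)
        l2 = AnimalModel(df, ped, "IgM", coding="sum").loglike(comp)
        assert l1 == pytest.approx(l2, abs=1e-6)

    def test_converged_llf_not_below_generating_components(self, small_recovery_sim):
        sim = small_recovery_sim
        m = AnimalModel(sim.phenotypes, sim.pedigree, "IgM")
        res = m.fit(se=False)
        truth = {"sigma2_A": 0.345, "sigma2_m": 0.0345, "sigma2_e": 0.7705}
        assert res.llf >= m.loglike(truth) - 1e-6

    def test_lrt_scale_invariance(self, small_recovery_sim):
        sim = small_recovery_sim
        df = sim.phenotypes.iloc[:600].reset_index(drop=True)
        ped = sim.pedigree.prune(df["animal"])
        stats = []
        for scale in (1.0, 3.7):
            d = df.copy()
            d["IgM"] = d["IgM"] * scale
            full = AnimalModel(d, ped, "IgM").fit(se=False)
            red = AnimalModel(d, ped, "IgM", maternal_env=False).fit(se=False)
            stats.append(lrt(full.llf, red.llf, 1)["statistic"])
        assert stats[0] == pytest.approx(stats[1], abs=5e-3)


class TestGlsMode:
    def test_fixed_components_give_exact_gls(self, small_recovery_sim):
        sim = small_recovery_sim
        df = sim.phenotypes.iloc[:250].reset_index(drop=True)
        ped = sim.pedigree.prune(df["animal"])
        comp = {"sigma2_A": 0.3, "sigma2_m": 0.05, "sigma2_e": 0.8}
        res = AnimalModel(df, ped, "IgM", fixed_components=comp).fit(se=False)
        # dense GLS at the same components
        A = relationship_matrix(ped).a_matrix
        n = len(df)
        ai = ped.indices(df["animal"])
        Za = np.zeros((n, ped.n))
        Za[np.arange(n), ai] = 1
        codes, _ = pd.factorize(df["dam_group"].astype(str), sort=True)
        Zm = np.zeros((n, codes.max() + 1))
        Zm[np.arange(n), codes] = 1
        V = (comp["sigma2_A"] * Za @ A @ Za.T + comp["sigma2_m"] * Zm @ Zm.T
             + comp["sigma2_e"] * np.eye(n))
        Vi = np.linalg.inv(V)
        m = AnimalModel(df, ped, "IgM")
        X, y = m.X, df["IgM"].to_numpy()
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        np.testing.assert_allclose(res.fe_params.to_numpy(), beta, atol=1e-8)


class TestInference:
    @pytest.mark.parametrize(
        "llf, llr, df, check",
        [
            (0.0, 0.0, 1, lambda r: r["statistic"] == 0 and r["p"] == 1.0),
            (13.15, 0.0, 1, lambda r: r["p"] < 0.001),
            (3.25, 0.0, 2, lambda r: abs(r["p"] - 0.0388) < 5e-3),
        ],
    )
    def test_lrt_tail_values(self, llf, llr, df, check):
        assert check(lrt(llf, llr, df))

    def test_lrt_negative_df_rejected(self):
        with pytest.raises(ValueError):
            lrt(1.0, 0.0, 0)

    def test_ratio_arithmetic(self):
        r = ratios({"sigma2_A": 0.345, "sigma2_m": 0.0345, "sigma2_e": 0.7705})
        assert r["h2"] == pytest.approx(0.30)
        assert r["m2"] == pytest.approx(0.03)
        assert ratios({"sigma2_A": 0.0, "sigma2_m": 0.1, "sigma2_e": 0.2})["h2"] == 0
        assert ratios({"sigma2_A": 0.4, "sigma2_m": 0.0, "sigma2_e": 0.0})["h2"] == 1
        with pytest.raises(ValueError):
            ratios({"sigma2_A": 0.0, "sigma2_m": 0.0, "sigma2_e": 0.0})


class TestGenotypeModel:
    @pytest.fixture(scope="class")
    def locus_fit(self, divergent_sim):
        sim = divergent_sim
        ph = sim.phenotypes
        sub = ph[ph["generation"] >= 2].reset_index(drop=True)
        ped = sim.pedigree.prune(sub["animal"])
        base = AnimalModel(sub, ped, "IgM").fit(se=False)
        comp = {k: base.components[k] for k in ("sigma2_A", "sigma2_m", "sigma2_e")}
        res = AnimalModel(
            sub, ped, "IgM", fixed=("plate", "sex", "line", "genotype"),
            fixed_components=comp,
        ).fit(se=False)
        return res

    def test_contrasts_follow_reparametrization(self, locus_fit):
        con = locus_fit.genotype_contrasts()
        cg = locus_fit.fe_params["genotype[CG]"]
        cc = locus_fit.fe_params["genotype[CC]"]
        assert con.loc["additive", "estimate"] == pytest.approx(cc / 2)
        assert con.loc["dominance", "estimate"] == pytest.approx(cg - cc / 2)

    def test_two_class_coding_refuses_contrasts(self, divergent_sim):
        sim = divergent_sim
        ph = sim.phenotypes.copy()
        ph["genotype"] = np.where(ph["genotype"] == "GG", "GG", "CG/CC")
        sub = ph[ph["generation"] >= 2].reset_index(drop=True)
        ped = sim.pedigree.prune(sub["animal"])
        res = AnimalModel(
            sub, ped, "IgM", fixed=("plate", "sex", "line", "genotype"),
            fixed_components={"sigma2_A": 0.4, "sigma2_m": 0.03, "sigma2_e": 0.8},
        ).fit(se=False)
        with pytest.raises(ValueError, match="3-class"):
            res.genotype_contrasts()

    def test_duplicated_interaction_term_raises(self, divergent_sim):
        sim = divergent_sim
        sub = sim.phenotypes[sim.phenotypes["generation"] >= 2].reset_index(drop=True)
        sub = sub.assign(genotype2=np.where(sub["genotype"] == "GG", "GG", "CG/CC"))
        ped = sim.pedigree.prune(sub["animal"])
        with pytest.raises(SingularDesignError):
            AnimalModel(
                sub, ped, "IgM",
                fixed=("plate", "sex", "genotype2", "genotype2", "genotype2:genotype2"),
                fixed_components={"sigma2_A": 0.4, "sigma2_m": 0.03, "sigma2_e": 0.8},
            )


class TestInteractions:
    def _fit_interaction(self, sim, extra=0.0, seed=0):
        """Fit genotype2 x sex with an optional injected sex-specific effect."""
        ph = sim.phenotypes.copy()
        ph["genotype2"] = np.where(ph["genotype"] == "GG", "GG", "CG/CC")
        if extra:
            bump = (ph["genotype2"] == "CG/CC") & (ph["sex"] == "M")
            ph.loc[bump, "IgM"] += extra
        sub = ph[ph["generation"] >= 2].reset_index(drop=True)
        ped = sim.pedigree.prune(sub["animal"])
        res = AnimalModel(
            sub, ped, "IgM",
            fixed=("plate", "sex", "line", "genotype2", "genotype2:sex"),
            fixed_components={"sigma2_A": 0.5, "sigma2_m": 0.035, "sigma2_e": 0.77},
        ).fit(se=False)
        return res

    def test_null_interaction_rarely_significant(self):
        cfg = default_config(
            n_base=400, generations=3, generation_sizes=(500, 500, 500),
            sires_selected=15, dams_selected=30,
        )
        hits = 0
        for seed in range(10):
            sim = run_experiment(cfg, seed=300 + seed)
            res = self._fit_interaction(sim)
            if res.wald_test("genotype2:sex")["p"] < 0.05:
                hits += 1
        assert hits <= 2

    def test_sex_specific_effect_recovered(self, divergent_sim):
        """Injected male-specific extra effect appears in the simple effects."""
        extra = 0.23  # male carriers get 1.15-0.92 more than female carriers
        res = self._fit_interaction(divergent_sim, extra=extra)
        female = res.contrast({"genotype2[CG/CC]": 1.0})
        male = res.contrast(
            {"genotype2[CG/CC]": 1.0, "genotype2[CG/CC]:sex[M]": 1.0}
        )
        diff = male["estimate"] - female["estimate"]
        se = np.sqrt(male["se"] ** 2 + female["se"] ** 2)
        assert abs(diff - extra) < 2 * se


class TestMaternalGenetic:
    def _sim(self, seed, s2mg=0.0):
        cfg = default_config(
            n_base=420, generations=1, generation_sizes=(450,),
            locus=LocusSpec(p0=0.45, genotype_values={}), select=False,
            sires_selected=20, dams_selected=40, n_ancestral_generations=1,
        )
        sim = run_experiment(cfg, seed=seed)
        if s2mg > 0:
            # inject a maternal genetic effect: dam's own breeding value scaled
            ph = sim.phenotypes.copy()
            tb = sim.truth.set_index("animal")["tbv_IgM"]
            dams = ph["dam"].astype(int)
            known = dams > 0
            gain = np.zeros(len(ph))
            gain[known.to_numpy()] = (
                np.sqrt(s2mg / 0.345) * tb.loc[dams[known].to_numpy()].to_numpy()
            )
            ph["IgM"] = ph["IgM"] + gain
            sim.phenotypes = ph
        return sim

    def _lrt_mg(self, sim):
        ph = sim.phenotypes[sim.phenotypes["dam"] > 0].reset_index(drop=True)
        ped = sim.pedigree
        m1 = AnimalModel(ph, ped, "IgM").fit(se=False)
        start = dict(m1.components)
        start["sigma2_mg"] = 0.1 * start["sigma2_A"]
        start["cov_a_mg"] = 0.0
        m4 = AnimalModel(ph, ped, "IgM", maternal_genetic=True).fit(
            se=False, start=start
        )
        return m1, m4, lrt(m4.llf, m1.llf, df=2)

    def test_null_rarely_significant_and_power_when_present(self):
        null_hits, power_hits = 0, 0
        for seed in range(6):
            _, m4, test = self._lrt_mg(self._sim(500 + seed))
            if test["p"] < 0.05:
                null_hits += 1
            r = m4.maternal_correlation()
            if r is not None and np.isfinite(r) and abs(r) > 0.99:
                assert m4.boundary_flags  # boundary estimates must be flagged
        for seed in range(6):
            _, _, test = self._lrt_mg(self._sim(600 + seed, s2mg=0.25))
            if test["p"] < 0.05:
                power_hits += 1
        assert null_hits <= 2
        assert power_hits >= 4


class TestTrendAndEbv:
    def test_founder_mean_ebv_near_zero(self, small_recovery_sim):
        sim = small_recovery_sim
        res = AnimalModel(sim.phenotypes, sim.pedigree, "IgM").fit(se=False)
        tr = genetic_trend(res)
        base = tr[tr["line"] == "base"]
        assert abs(base["mean_ebv"].iloc[0]) < 0.1

    def test_divergent_trend_directions(self, divergent_sim):
        res = AnimalModel(
            divergent_sim.phenotypes, divergent_sim.pedigree, "IgTotal"
        ).fit(se=False)
        tr = genetic_trend(res)
        last = tr[tr["generation"] == 4]
        hi = last.loc[last["line"] == "high", "mean_ebv"].iloc[0]
        lo = last.loc[last["line"] == "low", "mean_ebv"].iloc[0]
        assert hi > 0 > lo
        assert last.loc[last["line"] == "high", "mean_ebv_sigma_a"].iloc[0] > 0

    def test_component_se_and_ratio_se_available(self, small_recovery_sim):
        sim = small_recovery_sim
        df = sim.phenotypes.iloc[:600].reset_index(drop=True)
        ped = sim.pedigree.prune(df["animal"])
        res = AnimalModel(df, ped, "IgM").fit(se=True)
        assert set(res.component_se) == {"sigma2_A", "sigma2_m", "sigma2_e"}
        r = res.ratios()
        assert 0 < r["h2_se"] < 1
        assert "h2" in res.summary() and "variance components" in res.summary()
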