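import warnings

import numpy as np
import pandas as pd
import pytest

from nabsel.seltheory import LocusModel, locus_variances
from nabsel.simulate import (
    KinshipCache,
    LocusSpec,
    MatingWarning,
    SimConfig,
    TraitSpec,
    breed,
    default_config,
    elisa_titer,
    make_matings,
    phenotype,
    run_experiment,
    select_parents,
    simulate_base,
)


def flat_traits(**kw):
    base = dict(mean=5.0, sigma2_A=0.0, sigma2_m=0.0, sigma2_e=0.0,
                sigma2_plate=0.0, sex_effect=0.0)
    base.update(kw)
    return (TraitSpec("IgTotal", **base),)


class TestBase:
    def test_p0_zero_gives_all_gg(self):
        cfg = default_config(n_base=200, locus=LocusSpec(p0=0.0))
        cohort = simulate_base(cfg, np.random.default_rng(0))
        assert (cohort.genotype == 0).all()

    def test_zero_additive_variance_gives_zero_tbv(self):
        cfg = SimConfig(n_base=100, traits=flat_traits(), correlations=None)
        cohort = simulate_base(cfg, np.random.default_rng(0))
        assert np.all(cohort.tbv == 0)

    def test_hardy_weinberg_at_base_frequency(self):
        """Replicated founder draws match binomial sampling at p0 = 0.45."""
        cfg = default_config(n_base=10_000)
        rng = np.random.default_rng(3)
        freqs, het = [], []
        for _ in range(50):
            cohort = simulate_base(cfg, rng)
            freqs.append(cohort.genotype.mean() / 2)
            het.append((cohort.genotype == 1).mean())
        p, n = 0.45, 10_000
        se_p = np.sqrt(p * (1 - p) / (2 * n)) / np.sqrt(50)
        assert abs(np.mean(freqs) - p) < 3 * se_p
        exp_het = 2 * p * (1 - p)
        se_h = np.sqrt(exp_het * (1 - exp_het) / n) / np.sqrt(50)
        assert abs(np.mean(het) - exp_het) < 3 * se_h


class TestPhenotype:
    def test_deterministic_when_all_variances_zero(self):
        cfg = SimConfig(
            n_base=60, traits=flat_traits(sex_effect=-0.5), correlations=None,
            locus=LocusSpec(p0=0.45, genotype_values={}),
        )
        cohort = simulate_base(cfg, np.random.default_rng(1))
        ph = phenotype(cohort, cfg, np.random.default_rng(2), "G0")
        exp = np.where(ph["sex"] == "M", 4.5, 5.0)
        np.testing.assert_allclose(ph["IgTotal"], exp)

    def test_full_sibs_share_dam_effect(self):
        cfg = SimConfig(
            n_base=40, traits=flat_traits(sigma2_m=1.0), correlations=None,
            base_maternal_family_size=4,
            locus=LocusSpec(p0=0.45, genotype_values={}),
        )
        cohort = simulate_base(cfg, np.random.default_rng(1))
        ph = phenotype(cohort, cfg, np.random.default_rng(2), "G0")
        groups = ph.groupby("dam_group")["IgTotal"].nunique()
        assert (groups == 1).all()  # only the dam effect varies -> constant per family

    def test_base_variance_bookkeeping(self):
        """Base phenotypic variance = s2A + s2m + s2e + s2plate + locus variance."""
        cfg = default_config(n_base=5000)
        spec = next(t for t in cfg.traits if t.name == "IgM")
        locus = LocusModel(0.45, cfg.locus.values("IgM"))
        va, vd = locus_variances(locus)
        expected = spec.sigma2_P + spec.sigma2_plate + va + vd
        rng = np.random.default_rng(5)
        vars_ = []
        for _ in range(12):
            cohort = simulate_base(cfg, rng)
            ph = phenotype(cohort, cfg, rng, "G0")
            vars_.append(ph["IgM"].var(ddof=1))
        se = np.std(vars_, ddof=1) / np.sqrt(len(vars_))
        assert abs(np.mean(vars_) - expected) < 3 * max(se, 0.01)

    def test_missing_dam_label_raises(self):
        cfg = SimConfig(n_base=10, traits=flat_traits(sigma2_m=0.5), correlations=None)
        cohort = simulate_base(cfg, np.random.default_rng(0))
        cohort.dam_group = np.array([""] * cohort.n, dtype=object)
        with pytest.raises(ValueError, match="dam label"):
            phenotype(cohort, cfg, np.random.default_rng(0), "G0")


class TestSelectParents:
    def frame(self, vals, sexes=None, ids=None):
        n = len(vals)
        return pd.DataFrame(
            {
                "animal": ids if ids is not None else np.arange(1, n + 1),
                "sex": sexes if sexes is not None else ["M"] * n,
                "IgTotal": vals,
            }
        )

    def test_top_selection(self):
        df = self.frame([5.0, 3.0, 1.0, 2.0, 4.0], sexes=list("MMMFF"))
        sires, dams, _ = select_parents(df, "IgTotal", 2, 1, "high")
        assert set(sires) == {1, 2}
        assert list(dams) == [5]

    def test_low_direction_takes_bottom_and_flips_sign(self):
        rng = np.random.default_rng(0)
        df = self.frame(rng.standard_normal(2000), sexes=["M"] * 1000 + ["F"] * 1000)
        _, _, diffs = select_parents(df, "IgTotal", 500, 500, "low")
        assert diffs["M"] > 0.7  # effective downward selection, positive by convention

    def test_half_selected_differential_near_0_8(self):
        rng = np.random.default_rng(1)
        n = 200_000
        df = self.frame(rng.standard_normal(n), sexes=["M"] * n)
        _, _, diffs = select_parents(df, "IgTotal", n // 2, 0, "high")
        assert diffs["M"] == pytest.approx(0.7979, abs=0.01)

    def test_tie_resolved_by_animal_id(self):
        df = self.frame([1.0, 1.0, 1.0], ids=[30, 10, 20])
        sires, _, _ = select_parents(df, "IgTotal", 2, 0, "high")
        assert list(sires) == [10, 20]

    def test_too_few_candidates(self):
        with pytest.raises(ValueError, match="candidates"):
            select_parents(self.frame([1.0]), "IgTotal", 2, 0, "high")


class TestMatings:
    def _kin(self, parents):
        kin = KinshipCache()
        for a, s, d in parents:
            kin.add(a, s, d)
        return kin

    def test_unrelated_two_sires_four_dams(self):
        kin = self._kin([(i, None, None) for i in range(1, 7)])
        pairs = make_matings([1, 2], [3, 4, 5, 6], kin, 2, np.random.default_rng(0))
        counts = pd.Series([s for s, _ in pairs]).value_counts()
        assert (counts == 2).all()
        assert sorted(d for _, d in pairs) == [3, 4, 5, 6]

    def test_forced_fallback_warns(self):
        # one sire, one dam, full sibs: no sib-free assignment exists
        kin = self._kin([(1, None, None), (2, None, None),
                         (3, 1, 2), (4, 1, 2)])
        with pytest.warns(MatingWarning):
            pairs = make_matings([3], [4], kin, 2, np.random.default_rng(0))
        assert pairs == [(3, 4)]

    def test_sib_free_whenever_feasible(self):
        """Across random family structures a sib-free assignment is found
        whenever the bipartite compatibility graph admits one."""
        import networkx as nx

        rng = np.random.default_rng(12)
        for trial in range(25):
            n_fam = int(rng.integers(2, 5))
            founders = [(f, None, None) for f in range(100, 100 + 2 * n_fam)]
            kin = KinshipCache()
            for a, s, d in founders:
                kin.add(a, s, d)
            sires, dams = [], []
            aid = 0
            for f in range(n_fam):
                s0, d0 = 100 + 2 * f, 101 + 2 * f
                for _ in range(int(rng.integers(1, 4))):
                    kin.add(aid, s0, d0)
                    (sires if rng.random() < 0.5 else dams).append(aid)
                    aid += 1
            if not sires or not dams:
                continue
            ratio = 2
            # feasibility by maximum matching on the compatibility graph
            G = nx.Graph()
            for d in dams:
                for s in sires:
                    for r in range(ratio):
                        if {kin.sire[s], kin.dam[s]}.isdisjoint(
                            {kin.sire[d], kin.dam[d]}
                        ):
                            G.add_edge(("D", d), ("S", s, r))
            G.add_nodes_from([("D", d) for d in dams])
            match = nx.bipartite.maximum_matching(
                G, top_nodes=[("D", d) for d in dams]
            )
            feasible = sum(1 for d in dams if ("D", d) in match) == len(dams)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", MatingWarning)
                pairs = make_matings(sires, dams, kin, ratio, np.random.default_rng(trial))
            sib_pairs = sum(
                not {kin.sire[s], kin.dam[s]}.isdisjoint({kin.sire[d], kin.dam[d]})
                for s, d in pairs
            )
            if feasible:
                assert sib_pairs == 0


class TestBreed:
    def _setup(self, g_sire, g_dam, cfg=None):
        cfg = cfg or SimConfig(n_base=10, traits=flat_traits(sigma2_A=0.0),
                               correlations=None)
        kin = KinshipCache()
        kin.add(1, None, None)
        kin.add(2, None, None)
        parents = {
            "genotype": {1: g_sire, 2: g_dam},
            "tbv": {1: np.array([1.0]), 2: np.array([3.0])},
        }
        return cfg, kin, parents

    def test_cc_by_gg_gives_all_heterozygotes(self):
        cfg, kin, parents = self._setup(2, 0)
        off = breed([(1, 2)], np.array([500]), parents, cfg, kin,
                    np.random.default_rng(0), 10, 1, "high")
        assert (off.genotype == 1).all()

    def test_heterozygote_cross_segregates_1_2_1(self):
        cfg, kin, parents = self._setup(1, 1)
        n = 100_000
        off = breed([(1, 2)], np.array([n]), parents, cfg, kin,
                    np.random.default_rng(1), 10, 1, "high")
        props = np.bincount(off.genotype, minlength=3) / n
        for obs, exp in zip(props, (0.25, 0.5, 0.25)):
            assert abs(obs - exp) < 3 * np.sqrt(exp * (1 - exp) / n)

    def test_zero_variance_offspring_at_midparent(self):
        cfg, kin, parents = self._setup(1, 1)
        off = breed([(1, 2)], np.array([50]), parents, cfg, kin,
                    np.random.default_rng(2), 10, 1, "high")
        np.testing.assert_allclose(off.tbv[:, 0], 2.0)


class TestExperiment:
    def test_neutral_drift_preserves_frequency(self):
        """With selection off the mean frequency change over replicates is zero."""
        cfg = default_config(
            n_base=400, generations=3, generation_sizes=(300, 300, 300),
            select=False, sires_selected=15, dams_selected=30,
        )
        deltas = []
        for seed in range(30):
            sim = run_experiment(cfg, seed=seed)
            s = sim.summary
            for line in ("high", "low"):
                p7 = s.loc[(s["line"] == line) & (s["generation"] == 3), "freq_C"]
                deltas.append(float(p7.iloc[0]) - 0.45)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se

    def test_divergence_direction(self, divergent_sim):
        s = divergent_sim.summary
        last = s[s["generation"] == 4]
        low = last.loc[last["line"] == "low", "freq_C"].iloc[0]
        high = last.loc[last["line"] == "high", "freq_C"].iloc[0]
        assert low < high

    def test_generation_sizes_match_design(self):
        cfg = default_config(n_base=300, generations=2, generation_sizes=(530, 1134),
                             sires_selected=10, dams_selected=20)
        sim = run_experiment(cfg, seed=2)
        s = sim.summary.groupby("generation")["n"].sum()
        assert 526 <= s.loc[1] <= 1135 and 526 <= s.loc[2] <= 1135

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        cfg = default_config(n_base=150, generations=2, generation_sizes=(200, 200),
                             sires_selected=8, dams_selected=16)
        out = []
        for sub in ("a", "b"):
            sim = run_experiment(cfg, seed=99)
            d = tmp_path / sub
            sim.write(d)
            out.append({p.name: p.read_bytes() for p in d.iterdir()})
        assert out[0] == out[1]

    def test_pedigree_covers_all_phenotyped(self, divergent_sim):
        ids = set(divergent_sim.pedigree.ids)
        assert set(divergent_sim.phenotypes["animal"].astype(str)) <= ids


class TestElisaTiter:
    def test_worked_example(self):
        res = elisa_titer((1.9, 1.5, 0.8, 0.2), e_max=1.8)
        assert res.titer == pytest.approx(np.log2(640), abs=1e-9)
        assert not res.endpoint

    def test_all_above_target_flags_endpoint(self):
        res = elisa_titer((2.0, 1.9, 1.8, 1.7), e_max=1.0)
        assert res.titer == pytest.approx(np.log2(2560))
        assert res.endpoint

    def test_exact_tie_takes_lower_dilution(self):
        res = elisa_titer((1.2, 0.8, 0.1, 0.05), e_max=2.0)  # target 1.0
        assert res.titer == pytest.approx(np.log2(40))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            elisa_titer((), e_max=1.0)
        with pytest.raises(ValueError):
            elisa_titer((1.0,), e_max=0.0, dilutions=(40,))
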