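"""End-to-end orchestration: simulate -> fit -> trend -> theory -> report.

One structured configuration drives the whole analysis of a (synthetic)
divergent selection experiment: descriptive line comparisons, animal-model
variance components with the maternal-effect likelihood-ratio test, EBV
trends, major-locus fixed effects with additive/dominance contrasts, and
the deterministic theory comparison.  Replicates run on spawned child seeds
and are aggregated as mean +/- empirical SE.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import seltheory
from .model import AnimalModel, genetic_trend, lrt
from .simulate import LocusSpec, SimConfig, SimResult, TraitSpec, default_config, run_experiment

__all__ = ["RunConfig", "Report", "ConfigError", "load_config", "descriptives", "run_pipeline"]

log = logging.getLogger("nabsel")


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    sim: SimConfig = field(default_factory=default_config)
    seed: int = 1
    replicates: int = 1
    outdir: str | None = None
    fit_traits: tuple = ("IgM", "IgG", "IgTotal")
    fit_models: tuple = ("model1", "model2", "model5")
    bivariate_pairs: tuple = ()
    interaction_terms: tuple = ()
    theory: bool = True
    log_level: str = "INFO"

    def __post_init__(self):
        if self.replicates < 1:
            raise ConfigError("replicate count must be >= 1")
        missing = set(self.fit_traits) - set(self.sim.trait_names)
        if missing:
            raise ConfigError(f"fit traits not defined in the simulation: {sorted(missing)}")
        bad = set(self.fit_models) - {"model1", "model2", "model4", "model5"}
        if bad:
            raise ConfigError(f"unknown models: {sorted(bad)}")
        for pair in self.bivariate_pairs:
            if len(pair) != 2 or set(pair) - set(self.sim.trait_names):
                raise ConfigError(f"invalid bivariate pair: {pair}")
        bad = set(self.interaction_terms) - {"sex", "line", "generation"}
        if bad:
            raise ConfigError(f"unknown interaction terms: {sorted(bad)}")


def load_config(path) -> RunConfig:
    """Read a JSON run configuration.

    Unknown keys raise :class:`ConfigError` before any computation starts.
    """
    with open(path) as fh:
        raw = json.load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw)
    sim_raw = dict(raw.pop("sim", {}))
    known_sim = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(sim_raw) - known_sim
    if unknown:
        raise ConfigError(f"unknown sim config keys: {sorted(unknown)}")
    if "traits" in sim_raw:
        try:
            sim_raw["traits"] = tuple(TraitSpec(**t) for t in sim_raw["traits"])
        except TypeError as exc:
            raise ConfigError(f"invalid trait spec: {exc}") from exc
    if "locus" in sim_raw:
        loc = dict(sim_raw["locus"])
        loc["genotype_values"] = {
            k: tuple(v) for k, v in loc.get("genotype_values", {}).items()
        }
        sim_raw["locus"] = LocusSpec(**loc)
    if "generation_sizes" in sim_raw:
        sim_raw["generation_sizes"] = tuple(sim_raw["generation_sizes"])
    if "correlations" in sim_raw and sim_raw["correlations"] is not None:
        sim_raw["correlations"] = {
            k: np.asarray(v, float) for k, v in sim_raw["correlations"].items()
        }
    try:
        sim = SimConfig(**sim_raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid sim config: {exc}") from exc
    known = {f.name for f in dataclasses.fields(RunConfig)} - {"sim"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for key in ("fit_traits", "fit_models", "interaction_terms"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "bivariate_pairs" in raw:
        raw["bivariate_pairs"] = tuple(tuple(p) for p in raw["bivariate_pairs"])
    return RunConfig(sim=sim, **raw)


def descriptives(phenos: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-generation line means, SDs and High-Low Welch t-tests.

    Groups with fewer than two records get no SD (flagged); two groups with
    zero variance give p = 1 when their means coincide and p = 0 otherwise
    (the t statistic is degenerate there).
    """
    traits = traits or [
        c for c in ("IgM", "IgG", "IgTotal") if c in phenos.columns
    ]
    rows = []
    for gen, sub in phenos.groupby("generation", sort=True):
        for trait in traits:
            row = {"generation": gen, "trait": trait}
            groups = {}
            for line, g in sub.groupby("line"):
                vals = g[trait].dropna().to_numpy()
                groups[line] = vals
                row[f"mean_{line}"] = vals.mean() if vals.size else np.nan
                row[f"sd_{line}"] = vals.std(ddof=1) if vals.size > 1 else np.nan
                if vals.size < 2:
                    row[f"sd_flag_{line}"] = "n<2"
            if {"high", "low"} <= groups.keys():
                hi, lo = groups["high"], groups["low"]
                row["diff_high_low"] = hi.mean() - lo.mean()
                if hi.std() == 0 and lo.std() == 0:
                    row["p_value"] = 1.0 if hi.mean() == lo.mean() else 0.0
                else:
                    row["p_value"] = float(
                        stats.ttest_ind(hi, lo, equal_var=False).pvalue
                    )
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class Report:
    """Aggregated pipeline output tables."""

    descriptive: pd.DataFrame
    components: pd.DataFrame
    trend: pd.DataFrame
    genotype_effects: pd.DataFrame | None
    allele_frequencies: pd.DataFrame
    theory: pd.DataFrame | None
    replicate_summary: pd.DataFrame | None
    header: dict
    correlations: pd.DataFrame | None = None
    interactions: pd.DataFrame | None = None
    ebv: pd.DataFrame | None = None
    fixed_effects: pd.DataFrame | None = None

    def render(self) -> str:
        lines = ["nabsel pipeline report", "=" * 66]
        for k, v in self.header.items():
            lines.append(f"{k}: {v}")
        sections = [
            ("Descriptive statistics (line means, High-Low difference)", self.descriptive),
            ("Variance components and ratios [animal model, per trait]", self.components),
            ("Genetic trend (mean EBV by line x generation) [animal model]", self.trend),
            ("Major-locus genotype effects [locus model, components fixed]", self.genotype_effects),
            ("Bivariate correlations [two-trait animal model]", self.correlations),
            ("Major-locus interaction tests [2-class locus model]", self.interactions),
            ("Observed C-allele frequencies [simulation summary]", self.allele_frequencies),
            ("Deterministic theory trajectory [selection-theory module]", self.theory),
            ("Replicate aggregation (mean +/- SE)", self.replicate_summary),
        ]
        for title, df in sections:
            if df is None:
                continue
            lines += ["", title, "-" * 66, df.to_string(index=False)]
        return "\n".join(lines) + "\n"

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        kw = {"index": False, "float_format": "%.10g"}
        self.descriptive.to_csv(os.path.join(outdir, "descriptives.csv"), **kw)
        self.components.to_csv(os.path.join(outdir, "components.csv"), **kw)
        self.trend.to_csv(os.path.join(outdir, "trend.csv"), **kw)
        if self.genotype_effects is not None:
            self.genotype_effects.to_csv(
                os.path.join(outdir, "genotype_effects.csv"), **kw
            )
        self.allele_frequencies.to_csv(
            os.path.join(outdir, "allele_frequencies.csv"), **kw
        )
        if self.theory is not None:
            self.theory.to_csv(os.path.join(outdir, "theory.csv"), **kw)
        if self.replicate_summary is not None:
            self.replicate_summary.to_csv(
                os.path.join(outdir, "replicate_summary.csv"), **kw
            )
        for name in ("correlations", "interactions", "ebv", "fixed_effects"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(os.path.join(outdir, f"{name}.csv"), **kw)
        with open(os.path.join(outdir, "report.txt"), "w") as fh:
            fh.write(self.render())


def _analyse_one(sim: SimResult, config: RunConfig) -> dict:
    """All per-replicate analyses; returns tables + scalar summaries."""
    ph = sim.phenotypes
    out = {"scalars": {}}
    out["descriptive"] = descriptives(ph, list(config.fit_traits))

    comp_rows = []
    trends = []
    geno = []
    inter_rows = []
    ebv_cols = {}
    fe_rows = []
    for trait in config.fit_traits:
        res1 = None
        if "model1" in config.fit_models:
            res1 = AnimalModel(ph, sim.pedigree, trait).fit(se=False)
            r = res1.ratios()
            row = {
                "trait": trait,
                "model": "additive+maternal",
                **{k: round(v, 6) for k, v in res1.components.items()},
                "h2": r["h2"],
                "m2": r["m2"],
                "logL": res1.llf,
            }
            out["scalars"][f"h2_{trait}"] = r["h2"]
            out["scalars"][f"m2_{trait}"] = r["m2"]
            if "model2" in config.fit_models:
                res2 = AnimalModel(
                    ph, sim.pedigree, trait, maternal_env=False
                ).fit(se=False)
                test = lrt(res1.llf, res2.llf, df=1)
                row["lrt_maternal"] = test["statistic"]
                row["lrt_p"] = test["p"]
            comp_rows.append(row)
            tr = genetic_trend(res1)
            tr.insert(0, "trait", trait)
            trends.append(tr)
            ebv_cols[trait] = res1.ebv
            for nm, est, se_ in zip(
                res1.fe_params.index, res1.fe_params, res1.bse
            ):
                fe_rows.append(
                    {"trait": trait, "effect": nm, "estimate": est, "se": se_}
                )
            if "model4" in config.fit_models:
                with_dam = ph[ph["dam"].astype(int) > 0].reset_index(drop=True)
                if len(with_dam):
                    base4 = AnimalModel(with_dam, sim.pedigree, trait).fit(se=False)
                    start4 = dict(base4.components)
                    start4["sigma2_mg"] = 0.1 * start4["sigma2_A"]
                    start4["cov_a_mg"] = 0.0
                    res4 = AnimalModel(
                        with_dam, sim.pedigree, trait, maternal_genetic=True
                    ).fit(se=False, start=start4)
                    test4 = lrt(res4.llf, base4.llf, df=2)
                    comp_rows.append(
                        {
                            "trait": trait,
                            "model": "maternal-genetic",
                            **{k: round(v, 6) for k, v in res4.components.items()},
                            "logL": res4.llf,
                            "lrt_maternal_genetic": test4["statistic"],
                            "lrt_p": test4["p"],
                        }
                    )
            for ln in ("high", "low"):
                last = tr[(tr["line"] == ln) & (tr["generation"] == tr["generation"].max())]
                if len(last):
                    out["scalars"][f"trend_{trait}_{ln}"] = float(
                        last["mean_ebv"].iloc[0]
                    )
        if "model5" in config.fit_models and res1 is not None:
            sub = ph[ph["generation"] >= max(0, config.sim.generations - 2)]
            sub = sub.reset_index(drop=True)
            if sub["genotype"].nunique() > 1 and sub["line"].nunique() > 1:
                ped5 = sim.pedigree.prune(sub["animal"])
                comp5 = {
                    k: res1.components[k]
                    for k in ("sigma2_A", "sigma2_m", "sigma2_e")
                }

                def fit5(frame, geno_col):
                    return AnimalModel(
                        frame,
                        ped5,
                        trait,
                        fixed=("plate", "sex", "line", geno_col),
                        fixed_components=comp5,
                    ).fit(se=False)

                from .model import SingularDesignError

                res5 = None
                try:
                    res5 = fit5(sub, "genotype")
                    con = res5.genotype_contrasts()
                except SingularDesignError:
                    # rare genotype classes can alias with plates in small
                    # cohorts; fall back to the dominant 2-class coding
                    sub2 = sub.assign(
                        genotype=np.where(sub["genotype"] == "GG", "GG", "CG/CC")
                    )
                    try:
                        res5 = fit5(sub2, "genotype")
                    except SingularDesignError:
                        log.warning(
                            "%s: locus model confounded even with 2 genotype "
                            "classes; skipping", trait,
                        )
                    con = None
                for term in config.interaction_terms:
                    sub2 = sub.assign(
                        genotype2=np.where(sub["genotype"] == "GG", "GG", "CG/CC")
                    )
                    try:
                        res_i = AnimalModel(
                            sub2,
                            ped5,
                            trait,
                            fixed=("plate", "sex", "line", "genotype2",
                                   f"genotype2:{term}"),
                            fixed_components=comp5,
                        ).fit(se=False)
                        w = res_i.wald_test(f"genotype2:{term}")
                        inter_rows.append(
                            {"trait": trait, "term": term,
                             "wald_chi2": w["statistic"], "df": w["df"],
                             "p": w["p"]}
                        )
                    except SingularDesignError:
                        log.warning(
                            "%s: genotype x %s interaction aliased; skipped",
                            trait, term,
                        )
                if res5 is not None:
                    for key in res5.fe_params.index:
                        if key.startswith("genotype["):
                            gclass = key[len("genotype["):-1]
                            geno.append(
                                {
                                    "trait": trait,
                                    "effect": gclass,
                                    "estimate": res5.fe_params[key],
                                    "se": res5.bse[key],
                                }
                            )
                            out["scalars"][f"{gclass}_{trait}"] = float(
                                res5.fe_params[key]
                            )
                    if con is not None:
                        for eff in ("additive", "dominance"):
                            geno.append(
                                {
                                    "trait": trait,
                                    "effect": eff,
                                    "estimate": con.loc[eff, "estimate"],
                                    "se": con.loc[eff, "se"],
                                }
                            )

    corr_rows = []
    for t1, t2 in config.bivariate_pairs:
        from .bivariate import BivariateAnimalModel

        bres = BivariateAnimalModel(
            ph, sim.pedigree, (t1, t2), fixed=("plate",)
        ).fit()
        corr_rows.append(
            {
                "trait1": t1,
                "trait2": t2,
                "r_a": bres.r_a,
                "r_m": bres.r_m,
                "r_e": bres.r_e,
                "r_p": bres.r_p,
                "logL": bres.llf,
            }
        )
        out["scalars"][f"ra_{t1}_{t2}"] = float(bres.r_a)

    out["components"] = pd.DataFrame(comp_rows)
    out["trend"] = (
        pd.concat(trends, ignore_index=True) if trends else pd.DataFrame()
    )
    out["genotype_effects"] = pd.DataFrame(geno) if geno else None
    out["correlations"] = pd.DataFrame(corr_rows) if corr_rows else None
    out["interactions"] = pd.DataFrame(inter_rows) if inter_rows else None
    out["ebv"] = (
        pd.DataFrame(ebv_cols).rename_axis("animal").reset_index()
        if ebv_cols
        else None
    )
    out["fixed_effects"] = pd.DataFrame(fe_rows) if fe_rows else None

    freq = sim.summary[["generation", "line", "n", "freq_C", "mean_F"]].copy()
    out["allele_frequencies"] = freq
    for ln in ("high", "low"):
        last = freq[(freq["line"] == ln) & (freq["generation"] == config.sim.generations)]
        if len(last):
            out["scalars"][f"p7_{ln}"] = float(last["freq_C"].iloc[0])
    return out


def run_pipeline(config: RunConfig) -> Report:
    """Execute the configured stages and return the aggregated report."""
    logging.basicConfig(level=config.log_level)
    t_start = time.time()
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    per_rep = []
    failures = 0
    first = None
    for k, child in enumerate(children):
        t0 = time.time()
        try:
            sim = run_experiment(config.sim, seed=child)
            res = _analyse_one(sim, config)
            per_rep.append(res["scalars"])
            if first is None:
                first = (sim, res)
            log.info("replicate %d done in %.1fs", k, time.time() - t0)
        except Exception:  # pragma: no cover - defensive per-replicate guard
            failures += 1
            log.exception("replicate %d failed; skipping", k)
    if first is None:
        raise RuntimeError("every replicate failed")
    sim, res = first

    rep_summary = None
    if len(per_rep) > 1:
        rep_df = pd.DataFrame(per_rep)
        rep_summary = pd.DataFrame(
            {
                "quantity": rep_df.columns,
                "mean": rep_df.mean().to_numpy(),
                "se": (rep_df.std(ddof=1) / np.sqrt(len(rep_df))).to_numpy(),
                "n_reps": len(rep_df),
            }
        )

    theory_df = None
    if config.theory:
        locus = seltheory.LocusModel(
            p=config.sim.locus.p0,
            values=config.sim.locus.values(config.sim.selection_criterion),
        )
        spec = next(
            t for t in config.sim.traits if t.name == config.sim.selection_criterion
        )
        trait = seltheory.TraitGenetics(
            h2=spec.sigma2_A / spec.sigma2_P, sigma2_P=spec.sigma2_P
        )
        sizes = (config.sim.n_base,) + tuple(
            config.sim.generation_sizes[: config.sim.generations - 1]
        )
        scheme = seltheory.design_scheme(
            sizes, config.sim.sires_selected, config.sim.dams_selected
        )
        theory_df = seltheory.allele_trajectory(
            locus, scheme, trait, generations=config.sim.generations
        )

    log.info("pipeline finished in %.1fs", time.time() - t_start)
    # wall-clock timing is logged, not rendered: reports must be
    # byte-identical across runs with the same seed
    header = {
        "seed": config.seed,
        "replicates": f"{config.replicates} ({failures} failed)" if failures else config.replicates,
        "criterion": config.sim.selection_criterion,
        "records": len(sim.phenotypes),
        "status": "FAILURES" if failures else "ok",
    }
    report = Report(
        descriptive=res["descriptive"],
        components=res["components"],
        trend=res["trend"],
        genotype_effects=res["genotype_effects"],
        allele_frequencies=res["allele_frequencies"],
        theory=theory_df,
        replicate_summary=rep_summary,
        header=header,
        correlations=res.get("correlations"),
        interactions=res.get("interactions"),
        ebv=res.get("ebv"),
        fixed_effects=res.get("fixed_effects"),
    )
    if config.outdir:
        report.write(config.outdir)
        sim.write(os.path.join(config.outdir, "data"))
    return report
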