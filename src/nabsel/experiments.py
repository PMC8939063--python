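"""Replication experiments: deterministic theory values and synthetic-data
parameter recovery.

Each function reruns one quantitative check of the divergent
natural-antibody selection study from scratch: exact locus-response
arithmetic, the deterministic allele-frequency trajectory, and stochastic
recovery of heritability, maternal ratio, major-locus effect, endpoint
allele frequency and genetic correlation from data generated by
:mod:`nabsel.simulate` and re-estimated by the animal models.  The same
functions back both the acceptance script and the acceptance test suite.
"""

from __future__ import annotations

import numpy as np

from .bivariate import BivariateAnimalModel
from .model import AnimalModel
from .pedigree import Pedigree
from .seltheory import (
    LocusModel,
    TraitGenetics,
    allele_trajectory,
    design_scheme,
    locus_response_split,
)
from .simulate import LocusSpec, default_config, run_experiment

__all__ = [
    "IGM_LOCUS",
    "IGTOTAL_LOCUS",
    "recovery_config",
    "locus_decomposition",
    "trajectory_prediction",
    "h2_recovery",
    "genotype_effect_recovery",
    "endpoint_frequency",
    "bivariate_recovery",
]

#: major-locus genotype values (GG, CG, CC) in titer points
IGM_LOCUS = LocusModel(p=0.45, values=(0.0, 1.01, 1.12))
IGTOTAL_LOCUS = LocusModel(p=0.45, values=(0.0, 0.49, 0.44))


def recovery_config(**overrides):
    """Design for parameter-recovery experiments (~3,300 phenotyped animals).

    Three generations of the breeding design bred from a 600-bird base.
    The major locus is switched off and parents are drawn at random, so the
    generating polygenic components (and correlations) are exactly the
    documented trait defaults.
    """
    base = dict(
        n_base=600,
        generations=3,
        generation_sizes=(900, 900, 900),
        locus=LocusSpec(p0=0.45, genotype_values={}),
        select=False,
    )
    base.update(overrides)
    return default_config(**base)


def locus_decomposition() -> dict:
    """Locus and polygenic parts of the realized IgM genetic trends.

    The locus part is the change in the Hardy-Weinberg mean genotypic value
    between the base frequency and the generation-7 line frequencies; the
    polygenic part is the remainder of the realized trend.
    """
    low_locus, low_poly = locus_response_split(0.45, 0.04, IGM_LOCUS, -1.60)
    high_locus, high_poly = locus_response_split(0.45, 0.66, IGM_LOCUS, 1.13)
    return {
        "low_locus_part": low_locus,
        "low_polygenic_part": low_poly,
        "high_locus_part": high_locus,
        "high_polygenic_part": high_poly,
    }


def trajectory_prediction() -> dict:
    """Deterministic allele-frequency trajectory for IgTotal mass selection.

    Iterates dp = i p q alpha / sigma_P from p0 = 0.45 with the IgTotal
    locus values, sigma_P = sqrt(1.85), and sex-averaged intensities implied
    by selecting 25 sires / 50 dams per line from the per-generation
    candidate counts of the reference design.
    """
    trait = TraitGenetics(h2=0.12, sigma2_P=1.85)
    traj = allele_trajectory(IGTOTAL_LOCUS, design_scheme(), trait)
    last = traj[traj["generation"] == traj["generation"].max()]
    return {
        "high_p7": float(last.loc[last["line"] == "high", "p"].iloc[0]),
        "low_p7": float(last.loc[last["line"] == "low", "p"].iloc[0]),
        "trajectory": traj,
    }


def _spawn(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def _se(x: np.ndarray) -> float:
    """Empirical standard error of the mean (0 for a single replicate)."""
    x = np.asarray(x)
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


def h2_recovery(seed: int = 1, n_reps: int = 10, se: bool = False) -> dict:
    """REML recovery of the IgM heritability and maternal ratio.

    Simulates ``n_reps`` datasets under :func:`recovery_config` (generating
    sigma2_A = 0.345, sigma2_m = 0.0345, sigma2_e = 0.7705, so h2 = 0.30 and
    m2 = 0.03) and fits the animal model with plate and sex fixed and
    additive + dam random effects to each.
    """
    cfg = recovery_config()
    h2s, m2s = [], []
    for child in _spawn(seed, n_reps):
        sim = run_experiment(cfg, seed=child)
        res = AnimalModel(
            sim.phenotypes, sim.pedigree, "IgM", fixed=("plate", "sex")
        ).fit(se=se)
        r = res.ratios()
        h2s.append(r["h2"])
        m2s.append(r["m2"])
    h2s, m2s = np.asarray(h2s), np.asarray(m2s)
    return {
        "h2_mean": float(h2s.mean()),
        "h2_se": _se(h2s),
        "m2_mean": float(m2s.mean()),
        "m2_se": _se(m2s),
        "h2": h2s,
        "m2": m2s,
    }


def genotype_effect_recovery(seed: int = 1, n_reps: int = 10) -> dict:
    """Recovery of the CG-vs-GG IgM effect from the divergent experiment.

    Each replicate runs the full default design, estimates variance
    components by REML on the genotyped generations (5-7, pedigree pruned to
    those animals and their ancestors), then solves the major-locus model
    (plate, sex, line and 3-class genotype fixed; components held at the
    REML estimates) and records the CG coefficient.
    """
    cfg = default_config()
    cg, cc = [], []
    for child in _spawn(seed, n_reps):
        sim = run_experiment(cfg, seed=child)
        ph = sim.phenotypes
        sub = ph[ph["generation"] >= 5].reset_index(drop=True)
        ped = sim.pedigree.prune(sub["animal"])
        comp = AnimalModel(sub, ped, "IgM", fixed=("plate", "sex")).fit(se=False)
        res = AnimalModel(
            sub,
            ped,
            "IgM",
            fixed=("plate", "sex", "line", "genotype"),
            fixed_components={
                "sigma2_A": comp.components["sigma2_A"],
                "sigma2_m": comp.components["sigma2_m"],
                "sigma2_e": comp.components["sigma2_e"],
            },
        ).fit(se=False)
        cg.append(res.fe_params["genotype[CG]"])
        cc.append(res.fe_params["genotype[CC]"])
    cg, cc = np.asarray(cg), np.asarray(cc)
    return {
        "cg_mean": float(cg.mean()),
        "cg_se": _se(cg),
        "cc_mean": float(cc.mean()),
        "cc_se": _se(cc),
        "cg": cg,
        "cc": cc,
    }


def endpoint_frequency(seed: int = 1, n_reps: int = 100, reduced: bool = False) -> dict:
    """Generation-7 C-allele frequencies under the default divergent design.

    ``reduced=True`` shrinks the base population (the bulk of the records)
    while keeping the selected-line design intact, for quicker replicate
    batteries.
    """
    cfg = default_config(n_base=1200) if reduced else default_config()
    low, high = [], []
    for child in _spawn(seed, n_reps):
        sim = run_experiment(cfg, seed=child)
        s = sim.summary
        last = s[s["generation"] == cfg.generations]
        low.append(float(last.loc[last["line"] == "low", "freq_C"].iloc[0]))
        high.append(float(last.loc[last["line"] == "high", "freq_C"].iloc[0]))
    low, high = np.asarray(low), np.asarray(high)
    return {
        "low_p7_mean": float(low.mean()),
        "low_p7_se": _se(low),
        "high_p7_mean": float(high.mean()),
        "frac_low_below_high": float(np.mean(low < high)),
        "low": low,
        "high": high,
    }


def bivariate_recovery(seed: int = 1, n_reps: int = 10) -> dict:
    """Recovery of the IgM-IgTotal additive genetic correlation (0.91).

    Two-trait datasets are generated under :func:`recovery_config` with the
    documented correlation structure and refitted with the bivariate animal
    model (plate fixed, additive + dam + residual covariances free).
    """
    cfg = recovery_config()
    ras = []
    for child in _spawn(seed, n_reps):
        sim = run_experiment(cfg, seed=child)
        res = BivariateAnimalModel(
            sim.phenotypes, sim.pedigree, ("IgM", "IgTotal"), fixed=("plate",)
        ).fit()
        ras.append(res.r_a)
    ras = np.asarray(ras)
    return {
        "ra_mean": float(ras.mean()),
        "ra_se": _se(ras),
        "ra": ras,
    }
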