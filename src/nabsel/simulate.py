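"""Forward-in-time simulation of divergent mass selection with a major gene.

The generator emulates a poultry breeding design: a base population, then
seven generations of two lines (High / Low) divergently mass-selected on
total KLH-binding natural-antibody titer (IgTotal).  Each animal carries a
biallelic major locus (C/G, near-complete dominance of C), a polygenic
breeding value per trait (infinitesimal model), and a phenotype built as

    y = mean + plate + sex + genotype value + breeding value + dam + residual

with ELISA-plate effects shared by plate-mates, maternal environmental (dam)
effects shared by full sibs, and per-trait residuals.  Traits may be sampled
jointly from additive, maternal and residual correlation matrices; selection
always acts on the single criterion trait.

Every stage draws from a named child stream of one root seed, so an
identical seed and configuration reproduce output files byte for byte.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import Pedigree, build_pedigree

__all__ = [
    "TraitSpec",
    "LocusSpec",
    "SimConfig",
    "SimResult",
    "TiterResult",
    "default_config",
    "simulate_base",
    "phenotype",
    "select_parents",
    "make_matings",
    "breed",
    "run_experiment",
    "elisa_titer",
    "KinshipCache",
    "MatingWarning",
]

#: per-generation totals of the reference design (both lines combined)
DEFAULT_GENERATION_SIZES = (946, 820, 526, 915, 1135, 707, 974)


class MatingWarning(UserWarning):
    """A sib-free mating assignment was infeasible; fell back to least-related."""


@dataclass(frozen=True)
class TraitSpec:
    """Genetic architecture of one titer trait.

    Variances are in squared titer points; ``sigma2_A + sigma2_m + sigma2_e``
    is the phenotypic variance net of plate and major-locus contributions.
    ``sex_effect`` is the additive shift of males relative to females.
    """

    name: str
    mean: float
    sigma2_A: float
    sigma2_m: float
    sigma2_e: float
    sigma2_plate: float = 0.0
    sex_effect: float = 0.0

    def __post_init__(self):
        for f in ("sigma2_A", "sigma2_m", "sigma2_e", "sigma2_plate"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be non-negative")

    @property
    def sigma2_P(self) -> float:
        return self.sigma2_A + self.sigma2_m + self.sigma2_e


@dataclass(frozen=True)
class LocusSpec:
    """Major biallelic locus: base C-allele frequency and per-trait genotype values.

    ``genotype_values[trait] = (v_GG, v_CG, v_CC)`` in titer points.
    """

    p0: float = 0.45
    genotype_values: dict = field(
        default_factory=lambda: {
            "IgM": (0.0, 1.01, 1.12),
            "IgG": (0.0, 0.22, 0.07),
            "IgTotal": (0.0, 0.49, 0.44),
        }
    )

    def __post_init__(self):
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")

    def values(self, trait: str) -> tuple:
        return tuple(self.genotype_values.get(trait, (0.0, 0.0, 0.0)))


def _default_traits() -> tuple:
    # phenotypic variances / ratios of the reference population:
    # sigma2_P (A+m+e) 1.15 / 1.95 / 1.85, h2 0.30 / 0.12 / 0.12,
    # m2 0.03 / 0.02 / 0.03; plate variance from the fractions of total
    # variation explained by a random plate effect (18 / 14 / 22 %).
    return (
        TraitSpec("IgM", mean=7.10, sigma2_A=0.345, sigma2_m=0.0345,
                  sigma2_e=0.7705, sigma2_plate=0.2524, sex_effect=-0.13),
        TraitSpec("IgG", mean=6.16, sigma2_A=0.234, sigma2_m=0.039,
                  sigma2_e=1.677, sigma2_plate=0.3174),
        TraitSpec("IgTotal", mean=6.89, sigma2_A=0.222, sigma2_m=0.0555,
                  sigma2_e=1.5725, sigma2_plate=0.5218),
    )


def _default_correlations() -> dict:
    # order: IgM, IgG, IgTotal.  Additive and maternal values as reported;
    # the two unreported residual correlations are implied by the phenotypic
    # correlations (r_p identity), see the methods note.
    return {
        "additive": np.array(
            [[1.0, 0.77, 0.91], [0.77, 1.0, 0.94], [0.91, 0.94, 1.0]]
        ),
        "maternal": np.array(
            [[1.0, 0.41, 0.65], [0.41, 1.0, 0.87], [0.65, 0.87, 1.0]]
        ),
        "residual": np.array(
            [[1.0, 0.21, 0.461], [0.21, 1.0, 0.826], [0.461, 0.826, 1.0]]
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """Full parametrisation of the breeding design and trait architecture."""

    n_base: int = 4855
    generations: int = 7
    sires_selected: int = 25
    dams_selected: int = 50
    mating_ratio: int = 2
    generation_sizes: tuple = DEFAULT_GENERATION_SIZES
    traits: tuple = field(default_factory=_default_traits)
    locus: LocusSpec = field(default_factory=LocusSpec)
    correlations: dict | None = field(default_factory=_default_correlations)
    selection_criterion: str = "IgTotal"
    select: bool = True
    plate_size: int = 20
    base_female_fraction: float = 0.638  # 3099 of 4855
    base_maternal_family_size: int = 6
    n_ancestral_generations: int = 0
    confound_base_plates: bool = False
    plate_drift_sd: float = 0.0

    def __post_init__(self):
        if self.n_base <= 0 or self.generations < 0:
            raise ValueError("counts must be positive")
        if self.mating_ratio < 1:
            raise ValueError("mating_ratio must be >= 1")
        if self.sires_selected <= 0 or self.dams_selected <= 0:
            raise ValueError("selection counts must be positive")
        if len(self.generation_sizes) < self.generations:
            raise ValueError("generation_sizes shorter than generations")
        names = [t.name for t in self.traits]
        if self.selection_criterion not in names:
            raise ValueError(
                f"selection criterion {self.selection_criterion!r} not among traits {names}"
            )
        if self.correlations is not None:
            k = len(self.traits)
            for key, mat in self.correlations.items():
                m = np.asarray(mat)
                if m.shape != (k, k) or not np.allclose(m, m.T):
                    raise ValueError(f"{key} correlation matrix must be symmetric {k}x{k}")
                if np.any(np.diag(m) != 1.0):
                    raise ValueError(f"{key} correlation matrix must have unit diagonal")
                if np.linalg.eigvalsh(m).min() < -1e-8:
                    raise ValueError(f"{key} correlation matrix is not PSD")

    @property
    def trait_names(self) -> list:
        return [t.name for t in self.traits]


def default_config(**overrides) -> SimConfig:
    """The reference configuration of the selection experiment."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


@dataclass
class SimResult:
    """Pedigree + phenotypes + generating truth of one simulated experiment."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    summary: pd.DataFrame
    differentials: pd.DataFrame
    config: SimConfig

    def write(self, outdir) -> None:
        """Write pedigree / phenotype / truth / summary CSVs (10 sig. digits)."""
        import os

        os.makedirs(outdir, exist_ok=True)
        kw = {"index": False, "float_format": "%.10g"}
        self.pedigree.to_csv(os.path.join(outdir, "pedigree.csv"))
        self.phenotypes.to_csv(os.path.join(outdir, "phenotypes.csv"), **kw)
        self.truth.to_csv(os.path.join(outdir, "truth.csv"), **kw)
        self.summary.to_csv(os.path.join(outdir, "summary.csv"), **kw)
        self.differentials.to_csv(os.path.join(outdir, "differentials.csv"), **kw)


# ---------------------------------------------------------------------------
# kinship bookkeeping during simulation
# ---------------------------------------------------------------------------

class KinshipCache:
    """Memoised kinship coefficients on a growing pedigree.

    Kinship phi(i, j) is the probability of identity by descent of random
    alleles from i and j; F_offspring = phi(sire, dam) and
    F_i = 2 phi(s_i, d_i) ... = phi of its parents.  Recursion runs over the
    (small) ancestor graph of the selected parents only.
    """

    def __init__(self):
        self.sire: dict = {}
        self.dam: dict = {}
        self._memo: dict = {}
        self._order: dict = {}

    def add(self, animal: int, sire: int | None, dam: int | None):
        self.sire[animal] = sire
        self.dam[animal] = dam
        self._order[animal] = len(self._order)

    def phi(self, i: int | None, j: int | None) -> float:
        if i is None or j is None:
            return 0.0
        if i == j:
            key = (i, i)
            if key not in self._memo:
                self._memo[key] = 0.5 * (1.0 + self.phi(self.sire[i], self.dam[i]))
            return self._memo[key]
        if self._order[i] < self._order[j]:
            i, j = j, i
        key = (i, j)
        if key not in self._memo:
            self._memo[key] = 0.5 * (
                self.phi(self.sire[i], j) + self.phi(self.dam[i], j)
            )
        return self._memo[key]

    def inbreeding(self, animal: int) -> float:
        return self.phi(self.sire[animal], self.dam[animal])


# ---------------------------------------------------------------------------
# cohort container (plain arrays; assembled into DataFrames at the end)
# ---------------------------------------------------------------------------

@dataclass
class _Cohort:
    ids: np.ndarray           # int
    sire: np.ndarray          # int, 0 unknown
    dam: np.ndarray
    sex: np.ndarray           # 'M'/'F'
    generation: int
    line: np.ndarray          # str
    genotype: np.ndarray      # C-allele count 0/1/2
    tbv: np.ndarray           # (n, n_traits)
    dam_group: np.ndarray     # str label for maternal environmental sharing
    F: np.ndarray             # inbreeding coefficients

    @property
    def n(self) -> int:
        return self.ids.size


def _chol(corr: np.ndarray) -> np.ndarray:
    # tolerate semi-definite matrices via a tiny jitter
    k = corr.shape[0]
    return np.linalg.cholesky(corr + 1e-10 * np.eye(k))


def _mvn(rng, n, sds, corr) -> np.ndarray:
    """n draws of a zero-mean vector with given SDs and correlation matrix."""
    sds = np.asarray(sds, float)
    if corr is None or len(sds) == 1:
        return rng.standard_normal((n, len(sds))) * sds
    z = rng.standard_normal((n, len(sds)))
    return (z @ _chol(corr).T) * sds


def simulate_base(config: SimConfig, rng: np.random.Generator) -> _Cohort:
    """Founder cohort: Hardy-Weinberg genotypes, polygenic values, dam groups.

    With ``n_ancestral_generations == 0`` the founders receive pseudo
    maternal-family labels (blocks of ``base_maternal_family_size``) so that
    maternal environmental effects are defined; genetically they are
    unrelated founders.
    """
    n = config.n_base
    p = config.locus.p0
    geno = rng.binomial(2, p, n)
    sds = [np.sqrt(t.sigma2_A) for t in config.traits]
    corr = config.correlations["additive"] if config.correlations else None
    tbv = _mvn(rng, n, sds, corr)
    sex = np.where(rng.random(n) < config.base_female_fraction, "F", "M")
    order = rng.permutation(n)
    fam = np.empty(n, dtype=object)
    fam[order] = [
        f"BF{k // config.base_maternal_family_size}" for k in range(n)
    ]
    ids = np.arange(1, n + 1)
    return _Cohort(
        ids=ids,
        sire=np.zeros(n, dtype=np.int64),
        dam=np.zeros(n, dtype=np.int64),
        sex=sex,
        generation=0,
        line=np.full(n, "base", dtype=object),
        genotype=geno,
        tbv=tbv,
        dam_group=fam,
        F=np.zeros(n),
    )


def phenotype(
    cohort: _Cohort,
    config: SimConfig,
    rng: np.random.Generator,
    plate_prefix: str,
    mixed_plates: bool = True,
) -> pd.DataFrame:
    """Generate trait records for one cohort.

    Plates are consecutive blocks of ``plate_size`` after shuffling the
    cohort (mixing lines and sexes); with ``mixed_plates=False`` males and
    females are plated separately (the confounded base-population layout).
    Plate and dam effects are drawn per plate / dam group and shared.
    """
    n = cohort.n
    if any(t.sigma2_m > 0 for t in config.traits):
        if (pd.isna(cohort.dam_group) | (cohort.dam_group == "")).any():
            raise ValueError("animal without dam label while sigma2_m > 0")
    order = rng.permutation(n)
    if not mixed_plates:
        males = order[np.isin(order, np.where(cohort.sex == "M")[0])]
        females = order[np.isin(order, np.where(cohort.sex == "F")[0])]
        order = np.concatenate([males, females])
    plate_no = np.empty(n, dtype=np.int64)
    plate_no[order] = np.arange(n) // config.plate_size
    plates = np.array([f"{plate_prefix}P{j}" for j in plate_no], dtype=object)
    n_plates = plate_no.max() + 1

    corr = config.correlations
    t_sds = lambda f: [np.sqrt(getattr(t, f)) for t in config.traits]
    plate_eff = _mvn(rng, n_plates, t_sds("sigma2_plate"), None)  # independent per trait
    if config.plate_drift_sd > 0:
        plate_eff = plate_eff + rng.normal(
            0.0, config.plate_drift_sd, size=(1, len(config.traits))
        )
    dams, dam_codes = np.unique(cohort.dam_group, return_inverse=True)
    dam_eff = _mvn(rng, len(dams), t_sds("sigma2_m"), corr["maternal"] if corr else None)
    resid = _mvn(rng, n, t_sds("sigma2_e"), corr["residual"] if corr else None)

    male = (cohort.sex == "M").astype(float)
    out = {
        "animal": cohort.ids,
        "sire": cohort.sire,
        "dam": cohort.dam,
        "sex": cohort.sex,
        "line": cohort.line,
        "generation": cohort.generation,
        "plate": plates,
        "dam_group": cohort.dam_group,
        "genotype": np.array(["GG", "CG", "CC"], dtype=object)[cohort.genotype],
    }
    for j, t in enumerate(config.traits):
        gvals = np.asarray(config.locus.values(t.name))
        out[t.name] = (
            t.mean
            + plate_eff[plate_no, j]
            + t.sex_effect * male
            + gvals[cohort.genotype]
            + cohort.tbv[:, j]
            + dam_eff[dam_codes, j]
            + resid[:, j]
        )
    return pd.DataFrame(out)


def select_parents(
    phenos: pd.DataFrame,
    criterion: str,
    n_males: int,
    n_females: int,
    direction: str = "high",
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Within-sex truncation selection on own phenotype (mass selection).

    Returns selected sire ids, dam ids, and realized standardized selection
    differentials per sex, ``(mean selected - mean candidates) / SD
    candidates``, sign-flipped for the Low direction so that effective
    selection is positive.  Ties at the cutoff resolve by ascending animal
    id (stable, deterministic).
    """
    if direction not in {"high", "low"}:
        raise ValueError("direction must be 'high' or 'low'")
    chosen = {}
    diffs = {}
    for sex, need in (("M", n_males), ("F", n_females)):
        cand = phenos.loc[phenos["sex"] == sex, ["animal", criterion]].dropna()
        if len(cand) < need:
            raise ValueError(
                f"only {len(cand)} {sex} candidates for {need} requested"
            )
        if need == 0:
            chosen[sex] = np.empty(0, dtype=cand["animal"].dtype)
            diffs[sex] = 0.0
            continue
        vals = cand[criterion].to_numpy()
        ids = cand["animal"].to_numpy()
        keys = vals if direction == "low" else -vals
        order = np.lexsort((ids, keys))
        take = order[:need]
        sel = vals[take]
        sd = vals.std(ddof=1)
        s = (sel.mean() - vals.mean()) / sd if sd > 0 else 0.0
        diffs[sex] = -s if direction == "low" else s
        chosen[sex] = ids[take]
    return chosen["M"], chosen["F"], diffs


def make_matings(
    sires: np.ndarray,
    dams: np.ndarray,
    kin: KinshipCache,
    ratio: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Assign each dam to one sire (each sire serving at most ``ratio`` dams),
    avoiding full- and half-sib pairs.

    A sib-free assignment is found by maximum bipartite matching whenever one
    exists; leftover dams fall back to the least-related sire with capacity
    (fewest shared parents), with a warning.
    """
    import networkx as nx

    def shares_parent(s, d):
        ps = {kin.sire.get(s), kin.dam.get(s)} - {None}
        pd_ = {kin.sire.get(d), kin.dam.get(d)} - {None}
        return bool(ps & pd_)

    sires = [int(s) for s in rng.permutation(np.asarray(sires))]
    dams = [int(d) for d in rng.permutation(np.asarray(dams))]
    slots = [(s, r) for s in sires for r in range(ratio)]
    # integer-only node keys keep hashing (and thus matching order)
    # deterministic across processes
    G = nx.Graph()
    G.add_nodes_from([(0, d, 0) for d in dams], bipartite=0)
    G.add_nodes_from([(1, s, r) for s, r in slots], bipartite=1)
    for d in dams:
        for s, r in slots:
            if not shares_parent(s, d):
                G.add_edge((0, d, 0), (1, s, r))
    match = nx.bipartite.maximum_matching(G, top_nodes=[(0, d, 0) for d in dams])
    pairs = []
    used = {s: 0 for s in sires}
    unmatched = []
    for d in dams:
        node = match.get((0, d, 0))
        if node is None:
            unmatched.append(d)
            continue
        s = node[1]
        pairs.append((int(s), int(d)))
        used[s] += 1
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} dam(s) could not avoid sib matings; using "
            "least-related available sire",
            MatingWarning,
        )
        for d in unmatched:
            avail = [s for s in sires if used[s] < ratio] or sires
            scored = sorted(
                avail,
                key=lambda s: (
                    len(
                        ({kin.sire.get(s), kin.dam.get(s)} - {None})
                        & ({kin.sire.get(d), kin.dam.get(d)} - {None})
                    ),
                    kin.phi(int(s), int(d)),
                    used[s],
                ),
            )
            s = scored[0]
            used[s] += 1
            pairs.append((int(s), int(d)))
    return sorted(pairs)


def breed(
    matings: list,
    counts: np.ndarray,
    parents: dict,
    config: SimConfig,
    kin: KinshipCache,
    rng: np.random.Generator,
    start_id: int,
    generation: int,
    line: str,
) -> _Cohort:
    """Produce offspring: Mendelian locus transmission and polygenic values.

    The polygenic value is midparent plus a Mendelian-sampling deviation with
    variance ``0.5 sigma2_A (1 - (F_s + F_d) / 2)`` per trait (correlated
    across traits by the additive correlation matrix); the major-locus allele
    from each parent is an independent Bernoulli(genotype / 2) draw.
    """
    n = int(np.sum(counts))
    sire_arr = np.repeat([m[0] for m in matings], counts)
    dam_arr = np.repeat([m[1] for m in matings], counts)
    g_s = np.array([parents["genotype"][s] for s in sire_arr])
    g_d = np.array([parents["genotype"][d] for d in dam_arr])
    geno = rng.binomial(1, g_s / 2.0) + rng.binomial(1, g_d / 2.0)

    tbv_s = np.array([parents["tbv"][s] for s in sire_arr])
    tbv_d = np.array([parents["tbv"][d] for d in dam_arr])
    F_s = np.array([kin.phi(int(s), int(s)) * 2 - 1 for s in sire_arr])
    F_d = np.array([kin.phi(int(d), int(d)) * 2 - 1 for d in dam_arr])
    scale = np.sqrt(np.clip(0.5 * (1.0 - 0.5 * (F_s + F_d)), 0.0, None))
    sds = [np.sqrt(t.sigma2_A) for t in config.traits]
    corr = config.correlations["additive"] if config.correlations else None
    ms = _mvn(rng, n, sds, corr) * scale[:, None]
    tbv = 0.5 * (tbv_s + tbv_d) + ms

    ids = np.arange(start_id, start_id + n)
    F_off = np.array([kin.phi(int(s), int(d)) for s, d in zip(sire_arr, dam_arr)])
    return _Cohort(
        ids=ids,
        sire=sire_arr.astype(np.int64),
        dam=dam_arr.astype(np.int64),
        sex=np.where(rng.random(n) < 0.5, "F", "M"),
        generation=generation,
        line=np.full(n, line, dtype=object),
        genotype=geno,
        tbv=tbv,
        dam_group=np.array([f"D{d}" for d in dam_arr], dtype=object),
        F=F_off,
    )


def _distribute(total: int, k: int) -> np.ndarray:
    base, rem = divmod(total, k)
    out = np.full(k, base, dtype=np.int64)
    out[:rem] += 1
    return out


def run_experiment(config: SimConfig | None = None, seed: int | np.random.SeedSequence = 0) -> SimResult:
    """Run the full divergent selection experiment and collect outputs.

    Stages (base sampling, phenotyping, selection, mating, breeding) each use
    a dedicated child stream of the root seed.  With ``config.select=False``
    parents are drawn at random (drift-only control).
    """
    config = config or SimConfig()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("base", "ancestral", "phenotype", "selection", "mating", "breeding"),
            ss.spawn(6),
        )
    }

    kin = KinshipCache()
    cohorts = []
    next_id = 1

    base = simulate_base(config, streams["base"])
    if config.n_ancestral_generations > 0:
        base, next_id = _ancestral_rebuild(base, config, streams["ancestral"], kin)
        cohorts_extra = base[1]
        base = base[0]
        cohorts.extend(cohorts_extra)
    else:
        next_id = base.ids.max() + 1
    for a, s, d in zip(base.ids, base.sire, base.dam):
        kin.add(int(a), int(s) if s else None, int(d) if d else None)
    cohorts.append(base)

    pheno_frames = [
        phenotype(
            base, config, streams["phenotype"], "G0",
            mixed_plates=not config.confound_base_plates,
        )
    ]
    summaries = []
    diffs_rows = []

    def summarize(cohort, phenos):
        for ln in np.unique(cohort.line):
            m = cohort.line == ln
            row = {
                "generation": cohort.generation,
                "line": ln,
                "n": int(m.sum()),
                "freq_C": float(cohort.genotype[m].mean() / 2.0),
                "mean_F": float(cohort.F[m].mean()),
            }
            sub = phenos.loc[phenos["line"] == ln]
            for t in config.trait_names:
                row[f"mean_{t}"] = float(sub[t].mean())
                row[f"sd_{t}"] = float(sub[t].std(ddof=1))
                row[f"mean_tbv_{t}"] = float(
                    cohort.tbv[m, config.trait_names.index(t)].mean()
                )
            summaries.append(row)

    summarize(base, pheno_frames[0])

    parents_by_line = {}
    for ln, direction in (("high", "high"), ("low", "low")):
        if config.select:
            s_ids, d_ids, dd = select_parents(
                pheno_frames[0],
                config.selection_criterion,
                config.sires_selected,
                config.dams_selected,
                direction,
            )
        else:
            s_ids, d_ids, dd = _random_parents(
                pheno_frames[0], config, streams["selection"]
            )
        parents_by_line[ln] = (s_ids, d_ids)
        diffs_rows.append(
            {"generation": 0, "line": ln, "diff_M": dd.get("M", np.nan),
             "diff_F": dd.get("F", np.nan)}
        )

    lookup = {
        "genotype": dict(zip(base.ids, base.genotype)),
        "tbv": dict(zip(base.ids, base.tbv)),
    }

    for t in range(1, config.generations + 1):
        gen_cohorts = []
        for ln in ("high", "low"):
            s_ids, d_ids = parents_by_line[ln]
            pairs = make_matings(
                s_ids, d_ids, kin, config.mating_ratio, streams["mating"]
            )
            target = config.generation_sizes[t - 1] // 2
            counts = _distribute(target, len(pairs))
            cohort = breed(
                pairs, counts, lookup, config, kin, streams["breeding"],
                next_id, t, ln,
            )
            next_id += cohort.n
            for a, s, d in zip(cohort.ids, cohort.sire, cohort.dam):
                kin.add(int(a), int(s), int(d))
            lookup["genotype"].update(zip(cohort.ids, cohort.genotype))
            lookup["tbv"].update(zip(cohort.ids, cohort.tbv))
            gen_cohorts.append(cohort)

        merged = _merge_cohorts(gen_cohorts)
        cohorts.append(merged)
        ph = phenotype(merged, config, streams["phenotype"], f"G{t}")
        pheno_frames.append(ph)
        summarize(merged, ph)

        if t < config.generations:
            for ln, direction in (("high", "high"), ("low", "low")):
                sub = ph.loc[ph["line"] == ln]
                if config.select:
                    s_ids, d_ids, dd = select_parents(
                        sub,
                        config.selection_criterion,
                        config.sires_selected,
                        config.dams_selected,
                        direction,
                    )
                else:
                    s_ids, d_ids, dd = _random_parents(
                        sub, config, streams["selection"]
                    )
                parents_by_line[ln] = (s_ids, d_ids)
                diffs_rows.append(
                    {"generation": t, "line": ln, "diff_M": dd.get("M", np.nan),
                     "diff_F": dd.get("F", np.nan)}
                )

    ped_frame = pd.concat([_cohort_ped_frame(c) for c in cohorts], ignore_index=True)
    pedigree = build_pedigree(ped_frame)
    phenos = pd.concat(pheno_frames, ignore_index=True)
    truth_rows = []
    for c in cohorts:
        d = {
            "animal": c.ids,
            "line": c.line,
            "generation": c.generation,
            "genotype": c.genotype,
            "F": c.F,
            "dam_group": c.dam_group,
        }
        for j, t in enumerate(config.trait_names):
            d[f"tbv_{t}"] = c.tbv[:, j]
        truth_rows.append(pd.DataFrame(d))
    truth = pd.concat(truth_rows, ignore_index=True)
    return SimResult(
        pedigree=pedigree,
        phenotypes=phenos,
        truth=truth,
        summary=pd.DataFrame(summaries),
        differentials=pd.DataFrame(diffs_rows),
        config=config,
    )


def _random_parents(phenos, config, rng):
    males = phenos.loc[phenos["sex"] == "M", "animal"].to_numpy()
    females = phenos.loc[phenos["sex"] == "F", "animal"].to_numpy()
    s = rng.choice(males, config.sires_selected, replace=False)
    d = rng.choice(females, config.dams_selected, replace=False)
    return s, d, {"M": 0.0, "F": 0.0}


def _merge_cohorts(cohorts: list) -> _Cohort:
    return _Cohort(
        ids=np.concatenate([c.ids for c in cohorts]),
        sire=np.concatenate([c.sire for c in cohorts]),
        dam=np.concatenate([c.dam for c in cohorts]),
        sex=np.concatenate([c.sex for c in cohorts]),
        generation=cohorts[0].generation,
        line=np.concatenate([c.line for c in cohorts]),
        genotype=np.concatenate([c.genotype for c in cohorts]),
        tbv=np.vstack([c.tbv for c in cohorts]),
        dam_group=np.concatenate([c.dam_group for c in cohorts]),
        F=np.concatenate([c.F for c in cohorts]),
    )


def _cohort_ped_frame(c: _Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal": c.ids,
            "sire": c.sire,
            "dam": c.dam,
            "sex": c.sex,
            "generation": c.generation,
            "line": c.line,
        }
    )


def _ancestral_rebuild(base: _Cohort, config: SimConfig, rng, kin: KinshipCache):
    """Replace the founder cohort by offspring of an ancestral generation.

    One (or more) unphenotyped random-mating generation(s) give the base
    population real pedigree dams, so maternal-genetic models are estimable
    on it.  Family sizes follow ``base_maternal_family_size``.
    """
    n = config.n_base
    fam = config.base_maternal_family_size
    n_dams = int(np.ceil(n / fam))
    n_sires = max(1, n_dams // config.mating_ratio)
    next_id = 1
    prev_s = None
    prev_d = None
    extra_cohorts = []
    for g in range(config.n_ancestral_generations):
        n_anc = n_sires + n_dams
        geno = rng.binomial(2, config.locus.p0, n_anc)
        sds = [np.sqrt(t.sigma2_A) for t in config.traits]
        corr = config.correlations["additive"] if config.correlations else None
        if prev_s is None:
            tbv = _mvn(rng, n_anc, sds, corr)
            sire = np.zeros(n_anc, dtype=np.int64)
            dam = np.zeros(n_anc, dtype=np.int64)
        else:  # pragma: no cover - multi-ancestral layering rarely used
            sire = rng.choice(prev_s, n_anc)
            dam = rng.choice(prev_d, n_anc)
            tbv = _mvn(rng, n_anc, sds, corr)
        ids = np.arange(next_id, next_id + n_anc)
        next_id += n_anc
        sex = np.array(["M"] * n_sires + ["F"] * n_dams, dtype=object)
        anc = _Cohort(
            ids=ids, sire=sire, dam=dam, sex=sex, generation=0,
            line=np.full(n_anc, "base", dtype=object), genotype=geno, tbv=tbv,
            dam_group=np.array([f"A{g}_{i}" for i in ids], dtype=object),
            F=np.zeros(n_anc),
        )
        for a, s, d in zip(anc.ids, anc.sire, anc.dam):
            kin.add(int(a), int(s) if s else None, int(d) if d else None)
        extra_cohorts.append(anc)
        prev_s = ids[:n_sires]
        prev_d = ids[n_sires:]

    # base cohort bred from the last ancestral generation
    dams = prev_d[:n_dams]
    sires_for_dams = prev_s[rng.integers(0, len(prev_s), n_dams)]
    counts = _distribute(n, n_dams)
    pairs = list(zip(sires_for_dams, dams))
    lookup = {
        "genotype": {int(a): g for c in extra_cohorts for a, g in zip(c.ids, c.genotype)},
        "tbv": {int(a): t for c in extra_cohorts for a, t in zip(c.ids, c.tbv)},
    }
    cohort = breed(
        pairs, counts, lookup, config, kin, rng, next_id, 0, "base"
    )
    next_id += cohort.n
    # keep the configured base sex ratio
    cohort.sex = np.where(
        rng.random(cohort.n) < config.base_female_fraction, "F", "M"
    )
    return (cohort, extra_cohorts), next_id


# ---------------------------------------------------------------------------
# ELISA titer rule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TiterResult:
    titer: float
    endpoint: bool


def elisa_titer(
    extinctions,
    e_max: float,
    dilutions=(40, 160, 640, 2560),
) -> TiterResult:
    """log2 titer from a dilution series.

    The titer is ``log2`` of the dilution whose extinction lies closest to
    half the standard's maximum extinction; an exact tie between two
    dilutions resolves to the lower dilution.  ``endpoint`` flags a nearest
    point at either end of the series (titer outside the measured range).
    """
    ext = np.asarray(list(extinctions), float)
    if ext.size == 0:
        raise ValueError("empty extinction list")
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    dil = np.asarray(list(dilutions), float)
    if ext.size != dil.size:
        raise ValueError("extinctions and dilutions differ in length")
    target = 0.5 * e_max
    k = int(np.argmin(np.abs(ext - target)))  # argmin takes the first = lower dilution
    return TiterResult(titer=float(np.log2(dil[k])), endpoint=k in (0, ext.size - 1))
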