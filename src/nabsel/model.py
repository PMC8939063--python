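"""Pedigree-based mixed linear animal models: REML, BLUP and Wald inference.

The observation model is

    y = X b + Z_a a + (Z_g g) + (Z_m m) + e,

with ``a ~ N(0, A s2_A)`` the additive genetic effects (A the numerator
relationship matrix), optionally ``g ~ N(0, A s2_mg)`` maternal genetic
effects with direct-maternal covariance ``cov(a, g) = A s_a_mg``,
``m ~ N(0, I s2_m)`` maternal environmental (dam) effects, and residual
``e ~ N(0, I s2_e)``.  ELISA plate and sex enter as fixed factors; plate can
alternatively be fitted as a further identity-structured random effect.

Estimation maximises the restricted likelihood through the mixed-model
equations built on the sparse inverse of A.  Variance components are
expressed as ratios to the residual variance, which is then profiled out in
closed form; the reported ``llf`` is the full restricted log-likelihood
(constants included),

    llf = -1/2 [ (n-p) log 2 pi + log|V| + log|X' V^-1 X| - log|X' X| + y' P y ]

(the Patterson-Thompson form; the log|X'X| term makes the value invariant
to the fixed-effect coding).

Breeding values (EBVs) are the BLUP solutions at the converged components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from scipy import optimize, sparse, stats
from scipy.sparse.linalg import splu

from .pedigree import Pedigree, a_inverse

__all__ = [
    "AnimalModel",
    "AnimalModelResults",
    "SingularDesignError",
    "ConvergenceWarning",
    "build_fixed_design",
    "lrt",
    "ratios",
    "genetic_trend",
]

def _splu_spd(C: sparse.csc_matrix):
    """Sparse LU of the (SPD) mixed-model coefficient matrix.

    Symmetric-mode minimum-degree ordering keeps fill-in far below the
    default column ordering on pedigree-structured systems.
    """
    return splu(
        C,
        permc_spec="MMD_AT_PLUS_A",
        diag_pivot_thresh=0.01,
        options={"SymmetricMode": True},
    )


GENOTYPE_ORDER = ["GG", "CG", "CC"]
DOMINANT_ORDER = ["GG", "CG/CC"]


class SingularDesignError(ValueError):
    """The fixed-effect design is rank deficient (aliased columns)."""


class ConvergenceWarning(UserWarning):
    pass


# ---------------------------------------------------------------------------
# fixed-effects design
# ---------------------------------------------------------------------------

def _levels(values: pd.Series) -> list[str]:
    vals = pd.Series(values).astype(str)
    uniq = sorted(vals.unique())
    for canon in (GENOTYPE_ORDER, DOMINANT_ORDER):
        if set(uniq) <= set(canon):
            return [l for l in canon if l in uniq]
    return uniq


def _encode(values: pd.Series, name: str, coding: str) -> tuple[np.ndarray, list[str]]:
    """Dummy-code one categorical factor (first level is the reference)."""
    vals = pd.Series(values).astype(str).to_numpy()
    levels = _levels(values)
    if len(levels) < 2:
        return np.zeros((len(vals), 0)), []
    cols, names = [], []
    if coding == "treatment":
        for lev in levels[1:]:
            cols.append((vals == lev).astype(float))
            names.append(f"{name}[{lev}]")
    elif coding == "sum":
        last = vals == levels[-1]
        for lev in levels[:-1]:
            col = (vals == lev).astype(float)
            col[last] = -1.0
            cols.append(col)
            names.append(f"{name}[S.{lev}]")
    else:  # pragma: no cover
        raise ValueError(f"unknown coding {coding!r}")
    return np.column_stack(cols), names


def build_fixed_design(
    data: pd.DataFrame,
    terms,
    coding: str = "treatment",
    rank_check: bool = True,
) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Build the fixed-effects design matrix with an intercept.

    ``terms`` are column names treated as categorical factors; ``"a:b"``
    denotes an interaction (products of the two factors' non-reference
    dummies).  Returns the dense matrix, column names, and a term -> column
    slice map.  Raises :class:`SingularDesignError` naming aliased columns if
    the matrix is rank deficient (e.g. generation added next to plate).
    """
    n = len(data)
    cols = [np.ones((n, 1))]
    names = ["intercept"]
    term_slices = {"intercept": slice(0, 1)}
    start = 1
    for term in terms:
        if ":" in term:
            f1, f2 = term.split(":", 1)
            b1, n1 = _encode(data[f1], f1, coding)
            b2, n2 = _encode(data[f2], f2, coding)
            block = np.einsum("ij,ik->ijk", b1, b2).reshape(n, -1)
            bnames = [f"{a}:{b}" for a in n1 for b in n2]
        else:
            block, bnames = _encode(data[term], term, coding)
        cols.append(block)
        names.extend(bnames)
        term_slices[term] = slice(start, start + block.shape[1])
        start += block.shape[1]
    X = np.ascontiguousarray(np.hstack(cols))
    if rank_check:
        # cheap first pass on the (sparse) Gram matrix; the pivoted QR that
        # names aliased columns only runs when a deficiency is detected
        Xs = sparse.csr_matrix(X)
        gram = np.asarray((Xs.T @ Xs).todense())
        eig = np.linalg.eigvalsh(gram)
        tol = eig[-1] * max(X.shape) * np.finfo(float).eps * 100
        if eig[0] <= tol:
            from scipy.linalg import qr

            _, R, piv = qr(X, mode="economic", pivoting=True)
            diag = np.abs(np.diag(R))
            rtol = diag[0] * max(X.shape) * np.finfo(float).eps * 10
            rank = int((diag > rtol).sum())
            aliased = [names[j] for j in piv[rank:]]
            raise SingularDesignError(
                f"aliased fixed-effect columns: {aliased[:10]}"
                + (" ..." if len(aliased) > 10 else "")
            )
    return X, names, term_slices


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _embed(mat: sparse.spmatrix, row_off: int, col_off: int, size: int) -> sparse.csc_matrix:
    coo = mat.tocoo()
    return sparse.coo_matrix(
        (coo.data, (coo.row + row_off, coo.col + col_off)), shape=(size, size)
    ).tocsc()


@dataclass
class _Eval:
    llf: float
    sigma2_e: float
    theta: np.ndarray
    lu: object
    ypy: float


class AnimalModel:
    """Univariate animal model (responses one trait).

    Parameters
    ----------
    data : DataFrame
        One record per animal with the response, an ``animal`` column, the
        fixed-factor columns and, when a maternal environmental effect is
        fitted, a dam-group column (``maternal_group``, defaulting to
        ``dam_group`` if present, else ``dam``).
    pedigree : Pedigree
        Must cover every phenotyped animal.
    response : str
        Trait column name.
    fixed : sequence of str
        Fixed factor terms; ``"a:b"`` adds an interaction.
    maternal_env, maternal_genetic, random_plate : bool
        Random terms besides the additive genetic effect.
    fixed_components : dict, optional
        Components (``sigma2_A``, ``sigma2_m``, ``sigma2_mg``, ``cov_a_mg``,
        ``sigma2_plate``, ``sigma2_e``) to hold constant.  With every active
        component fixed, :meth:`fit` reduces to one generalised-least-squares
        solve (the major-locus model of the study is run this way).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        pedigree: Pedigree,
        response: str,
        fixed=("plate", "sex"),
        maternal_env: bool = True,
        maternal_genetic: bool = False,
        random_plate: bool = False,
        maternal_group: str | None = None,
        fixed_components: dict | None = None,
        coding: str = "treatment",
    ):
        data = data.loc[data[response].notna()].reset_index(drop=True)
        if not len(data):
            raise ValueError(f"no observations for {response!r}")
        self.data = data
        self.ped = pedigree
        self.response = response
        self.fixed = tuple(fixed)
        self.maternal_env = maternal_env
        self.maternal_genetic = maternal_genetic
        self.random_plate = random_plate
        self.fixed_components = dict(fixed_components or {})

        self.y = data[response].to_numpy(float)
        self.nobs = self.y.size
        self.X, self.fe_names, self.term_slices = build_fixed_design(
            data, self.fixed, coding=coding
        )
        self.p = self.X.shape[1]

        n_ped = pedigree.n
        rec_animal = pedigree.indices(data["animal"])
        rows = np.arange(self.nobs)
        Za = sparse.coo_matrix(
            (np.ones(self.nobs), (rows, rec_animal)), shape=(self.nobs, n_ped)
        ).tocsr()

        blocks = [sparse.csr_matrix(self.X), Za]
        off = self.p
        self._off_a = off
        off += n_ped
        self._off_g = None
        if maternal_genetic:
            dam_ix = pedigree.dam[rec_animal]
            if (dam_ix < 0).any():
                raise ValueError(
                    "maternal-genetic model requires a known dam for every "
                    "phenotyped animal"
                )
            Zg = sparse.coo_matrix(
                (np.ones(self.nobs), (rows, dam_ix)), shape=(self.nobs, n_ped)
            ).tocsr()
            blocks.append(Zg)
            self._off_g = off
            off += n_ped
        self._off_m = None
        self.n_dam = 0
        if maternal_env:
            col = maternal_group or ("dam_group" if "dam_group" in data else "dam")
            if col not in data:
                raise ValueError(
                    f"maternal grouping column {col!r} missing while a maternal "
                    "environmental variance is fitted"
                )
            grp = data[col]
            if grp.isna().any() or (grp.astype(str) == "0").any():
                raise ValueError(
                    "animal without dam label while a maternal environmental "
                    "variance is fitted"
                )
            codes, self.dam_levels = pd.factorize(grp.astype(str), sort=True)
            self.n_dam = len(self.dam_levels)
            Zm = sparse.coo_matrix(
                (np.ones(self.nobs), (rows, codes)), shape=(self.nobs, self.n_dam)
            ).tocsr()
            blocks.append(Zm)
            self._off_m = off
            off += self.n_dam
        self._off_pl = None
        self.n_plate = 0
        if random_plate:
            codes, self.plate_levels = pd.factorize(data["plate"].astype(str), sort=True)
            self.n_plate = len(self.plate_levels)
            Zp = sparse.coo_matrix(
                (np.ones(self.nobs), (rows, codes)), shape=(self.nobs, self.n_plate)
            ).tocsr()
            blocks.append(Zp)
            self._off_pl = off
            off += self.n_plate
        self._m = off

        W = sparse.hstack(blocks).tocsr()
        # Patterson-Thompson invariance: subtracting log|X'X| makes the
        # restricted likelihood independent of the fixed-effect coding
        self._logdet_xtx = float(np.linalg.slogdet(self.X.T @ self.X)[1])
        self._WtW = (W.T @ W).tocsc()
        self._Wty = np.asarray(W.T @ self.y).ravel()
        self._yty = float(self.y @ self.y)
        self._W = W

        Ainv = a_inverse(pedigree)
        self._logdet_a = pedigree.log_det_a()
        M = self._m
        self._P_aa = _embed(Ainv, self._off_a, self._off_a, M)
        if maternal_genetic:
            self._P_gg = _embed(Ainv, self._off_g, self._off_g, M)
            cross = _embed(Ainv, self._off_a, self._off_g, M)
            self._P_ag = (cross + cross.T).tocsc()
        if maternal_env:
            eye = sparse.identity(self.n_dam, format="coo")
            self._P_m = _embed(eye, self._off_m, self._off_m, M)
        if random_plate:
            eye = sparse.identity(self.n_plate, format="coo")
            self._P_pl = _embed(eye, self._off_pl, self._off_pl, M)

    # -- likelihood --------------------------------------------------------

    def component_names(self) -> list[str]:
        names = ["sigma2_A"]
        if self.maternal_genetic:
            names += ["sigma2_mg", "cov_a_mg"]
        if self.maternal_env:
            names.append("sigma2_m")
        if self.random_plate:
            names.append("sigma2_plate")
        names.append("sigma2_e")
        return names

    def _evaluate(self, comp: dict, profile: bool) -> _Eval:
        """Restricted log-likelihood at given components.

        When ``profile`` is true, ``comp['sigma2_e']`` is interpreted as 1 and
        all other entries as ratios to the residual variance, which is then
        estimated in closed form.
        """
        s2e = 1.0 if profile else comp["sigma2_e"]
        lam = {k: v / s2e for k, v in comp.items() if k != "sigma2_e"}

        C = self._WtW.copy()
        log_g = 0.0
        n_ped = self.ped.n
        if self.maternal_genetic:
            la, lg, c = lam["sigma2_A"], lam["sigma2_mg"], lam["cov_a_mg"]
            det = la * lg - c * c
            if det <= 0 or la <= 0:
                return _Eval(-np.inf, s2e, None, None, np.nan)
            C = C + (lg / det) * self._P_aa + (la / det) * self._P_gg - (c / det) * self._P_ag
            log_g += n_ped * np.log(det) + 2.0 * self._logdet_a
        else:
            C = C + (1.0 / lam["sigma2_A"]) * self._P_aa
            log_g += n_ped * np.log(lam["sigma2_A"]) + self._logdet_a
        if self.maternal_env:
            C = C + (1.0 / lam["sigma2_m"]) * self._P_m
            log_g += self.n_dam * np.log(lam["sigma2_m"])
        if self.random_plate:
            C = C + (1.0 / lam["sigma2_plate"]) * self._P_pl
            log_g += self.n_plate * np.log(lam["sigma2_plate"])

        lu = _splu_spd(C.tocsc())
        theta = lu.solve(self._Wty)
        ypy = self._yty - float(theta @ self._Wty)
        logdet_c = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        np_ = self.nobs - self.p
        if profile:
            s2e = ypy / np_
            quad = np_
        else:
            quad = ypy / s2e
        if s2e <= 0 or not np.isfinite(s2e):
            return _Eval(-np.inf, s2e, theta, lu, ypy)
        m2ll = (
            np_ * np.log(2 * np.pi) + np_ * np.log(s2e) + log_g + logdet_c
            + quad - self._logdet_xtx
        )
        return _Eval(-0.5 * m2ll, s2e, theta, lu, ypy)

    def loglike(self, components: dict) -> float:
        """Restricted log-likelihood at absolute variance components."""
        comp = {k: components[k] for k in self.component_names()}
        return self._evaluate(comp, profile=False).llf

    # -- fitting -----------------------------------------------------------

    def _free_names(self) -> list[str]:
        return [k for k in self.component_names() if k not in self.fixed_components]

    def fit(self, start: dict | None = None, se: bool = True, maxiter: int = 200) -> "AnimalModelResults":
        """Estimate free variance components by REML and return results.

        Free variances are optimised on a log scale (the direct-maternal
        covariance through a bounded correlation) with Nelder-Mead.  With no
        fixed components the residual variance is profiled out in closed
        form; with fixed components the free ones are optimised on the
        absolute scale.  ``se=False`` skips the numerical-Hessian standard
        errors of the components.
        """
        names = self.component_names()
        free = self._free_names()
        fixed = dict(self.fixed_components)
        # profiling is only unambiguous when nothing is held at an absolute value
        profile = not fixed
        opt_names = [k for k in free if not (profile and k == "sigma2_e")]

        # starting values
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        vr = float(np.var(self.y - self.X @ beta0))
        scale0 = 1.0 if profile else 0.6 * vr
        defaults = {
            "sigma2_A": 0.5 * scale0,
            "sigma2_m": 0.1 * scale0,
            "sigma2_mg": 0.05 * scale0,
            "cov_a_mg": 0.0,
            "sigma2_plate": 0.3 * scale0,
            "sigma2_e": 0.6 * vr,
        }
        if start:
            if profile and "sigma2_e" in start:
                s0 = start["sigma2_e"]
                defaults.update(
                    {k: v / s0 for k, v in start.items() if k != "sigma2_e"}
                )
            else:
                defaults.update(start)

        def pack(comp: dict) -> np.ndarray:
            x = []
            for k in opt_names:
                if k == "cov_a_mg":
                    r = comp[k] / max(np.sqrt(comp["sigma2_A"] * comp["sigma2_mg"]), 1e-12)
                    x.append(np.arctanh(np.clip(r, -0.99, 0.99)))
                else:
                    x.append(np.log(max(comp[k], 1e-10)))
            return np.array(x)

        def unpack(x: np.ndarray) -> dict:
            vals = dict(zip(opt_names, x))
            comp = {}
            for k in names:
                if k in fixed:
                    comp[k] = fixed[k]
                elif k == "sigma2_e" and profile:
                    comp[k] = 1.0
                elif k == "cov_a_mg":
                    continue
                else:
                    comp[k] = np.exp(vals[k])
            if "cov_a_mg" in names and "cov_a_mg" not in fixed:
                comp["cov_a_mg"] = np.tanh(vals["cov_a_mg"]) * np.sqrt(
                    comp["sigma2_A"] * comp["sigma2_mg"]
                )
            return comp

        n_iter = 0
        converged = True
        if opt_names:
            x0 = pack(defaults)

            def objective(x):
                comp = unpack(x)
                ev = self._evaluate(comp, profile=profile)
                return -ev.llf if np.isfinite(ev.llf) else 1e12

            # fatol is matched to a 1e-8 *relative* log-likelihood change
            f_scale = max(abs(self._evaluate(unpack(x0), profile=profile).llf), 1.0)
            res = optimize.minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={
                    "xatol": 1e-6,
                    "fatol": 1e-8 * f_scale,
                    "maxfev": maxiter * max(1, len(x0)) * 5,
                    "adaptive": len(x0) > 3,
                },
            )
            n_iter = res.nit
            converged = bool(res.success)
            if not converged:
                warnings.warn("REML did not converge", ConvergenceWarning)
            best = unpack(res.x)
        else:
            best = unpack(np.array([]))

        ev = self._evaluate(best, profile=profile)
        s2e = ev.sigma2_e
        components = {}
        for k in names:
            if k in fixed:
                components[k] = float(fixed[k])
            elif k == "sigma2_e":
                components[k] = float(s2e)
            else:
                components[k] = float(best[k] * (s2e if profile else 1.0))

        flags = []
        if self.maternal_genetic:
            sa, sg = components["sigma2_A"], components["sigma2_mg"]
            if sa > 0 and sg > 0:
                r = components["cov_a_mg"] / np.sqrt(sa * sg)
                if abs(r) > 0.99:
                    flags.append(
                        "direct-maternal genetic correlation at the boundary of "
                        "the parameter space"
                    )
            if sg < 1e-8 * max(components["sigma2_e"], 1e-12):
                flags.append("maternal genetic variance at zero boundary")
        for k in ("sigma2_A", "sigma2_m", "sigma2_plate"):
            if k in components and k not in fixed and components[k] < 1e-8 * components["sigma2_e"]:
                flags.append(f"{k} at zero boundary")

        comp_se = None
        comp_cov = None
        if se and free:
            comp_se, comp_cov = self._component_se(components)

        return AnimalModelResults(
            model=self,
            components=components,
            component_se=comp_se,
            component_cov=comp_cov,
            llf=float(ev.llf),
            converged=converged,
            n_iter=n_iter,
            boundary_flags=flags,
            _theta=ev.theta,
            _lu=ev.lu,
        )

    def _component_se(self, components: dict):
        """Numerical-Hessian standard errors on the natural component scale."""
        names = self._free_names()
        x0 = np.array([components[k] for k in names])

        def f(x):
            if np.any(x[[k for k, nm in enumerate(names) if nm != "cov_a_mg"]] <= 0):
                return -1e12
            comp = dict(components)
            comp.update(dict(zip(names, x)))
            val = self._evaluate(comp, profile=False).llf
            return val if np.isfinite(val) else -1e12

        k = len(x0)
        h = 1e-3 * np.maximum(np.abs(x0), 1e-3)
        H = np.zeros((k, k))
        f0 = f(x0)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h[i]
                ej = np.zeros(k); ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            cov = np.linalg.inv(-H)
            var = np.clip(np.diag(cov), 0, None)
            ses = dict(zip(names, np.sqrt(var)))
            return ses, pd.DataFrame(cov, index=names, columns=names)
        except np.linalg.LinAlgError:  # pragma: no cover
            return None, None


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class AnimalModelResults:
    """REML/BLUP fit of an :class:`AnimalModel`."""

    model: AnimalModel
    components: dict
    component_se: dict | None
    component_cov: pd.DataFrame | None
    llf: float
    converged: bool
    n_iter: int
    boundary_flags: list = field(default_factory=list)
    _theta: np.ndarray | None = None
    _lu: object = None

    # -- fixed effects -----------------------------------------------------

    @property
    def fe_params(self) -> pd.Series:
        return pd.Series(self._theta[: self.model.p], index=self.model.fe_names)

    @cached_property
    def cov_fe(self) -> pd.DataFrame:
        # the stored factorisation is always on the ratio-to-residual scale,
        # so Cov(b) = sigma2_e * C^-1 (upper-left block)
        m = self.model
        rhs = np.zeros((m._m, m.p))
        rhs[: m.p, :] = np.eye(m.p)
        sol = self._lu.solve(rhs)
        cov = sol[: m.p, :] * self.components["sigma2_e"]
        cov = 0.5 * (cov + cov.T)
        return pd.DataFrame(cov, index=m.fe_names, columns=m.fe_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_fe)), index=self.model.fe_names)

    # -- breeding values ---------------------------------------------------

    @cached_property
    def ebv(self) -> pd.Series:
        m = self.model
        vals = self._theta[m._off_a : m._off_a + m.ped.n]
        return pd.Series(vals, index=m.ped.ids, name="ebv")

    # -- ratios ------------------------------------------------------------

    def ratios(self) -> dict:
        """h2 and m2 (+ delta-method SEs when component covariances exist)."""
        return ratios(self.components, self.component_cov)

    @property
    def h2(self) -> float:
        return self.ratios()["h2"]

    @property
    def m2(self) -> float:
        return self.ratios().get("m2", 0.0)

    @property
    def sigma_a(self) -> float:
        """Additive genetic standard deviation."""
        return float(np.sqrt(self.components["sigma2_A"]))

    def maternal_correlation(self) -> float | None:
        """Implied direct-maternal genetic correlation (Model-4 style fits)."""
        if "sigma2_mg" not in self.components:
            return None
        sa = self.components["sigma2_A"]
        sg = self.components["sigma2_mg"]
        if sa <= 0 or sg <= 0:
            return np.nan
        return float(self.components["cov_a_mg"] / np.sqrt(sa * sg))

    # -- Wald inference ----------------------------------------------------

    def contrast(self, weights: dict) -> dict:
        """Wald test of a linear contrast of fixed effects.

        ``weights`` maps coefficient names to contrast weights.
        """
        L = np.zeros(self.model.p)
        names = self.model.fe_names
        for k, w in weights.items():
            L[names.index(k)] += w
        est = float(L @ self.fe_params.to_numpy())
        var = float(L @ self.cov_fe.to_numpy() @ L)
        se = np.sqrt(var)
        z = est / se if se > 0 else np.nan
        p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        return {"estimate": est, "se": se, "z": z, "p": p}

    def genotype_contrasts(self, term: str = "genotype") -> pd.DataFrame:
        """Additive = (CC - GG)/2 and dominance = CG - (CC + GG)/2 contrasts.

        Requires the three-class genotype factor; a two-class (dominant)
        coding cannot separate additive from dominance effects.
        """
        names = self.model.fe_names
        cc, cg = f"{term}[CC]", f"{term}[CG]"
        if cc not in names or cg not in names:
            raise ValueError(
                "genotype must be fitted as a 3-class factor (GG/CG/CC) for "
                "additive and dominance contrasts; use the 3-class coding "
                "instead of the dominant 2-class one"
            )
        rows = {
            "additive": self.contrast({cc: 0.5}),
            "dominance": self.contrast({cg: 1.0, cc: -0.5}),
        }
        return pd.DataFrame(rows).T

    def wald_test(self, term: str) -> dict:
        """Joint Wald chi-square test that all coefficients of ``term`` are 0."""
        sl = self.model.term_slices[term]
        b = self.fe_params.to_numpy()[sl]
        V = self.cov_fe.to_numpy()[sl, sl]
        stat = float(b @ np.linalg.solve(V, b))
        df = b.size
        return {"statistic": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}

    # -- reporting ---------------------------------------------------------

    def summary(self, max_fe: int = 15) -> str:
        m = self.model
        lines = [
            "Animal model REML fit",
            "=" * 60,
            f"response: {m.response}    n records: {m.nobs}    n pedigree: {m.ped.n}",
            f"fixed: {' + '.join(('intercept',) + m.fixed)}",
            f"restricted logL: {self.llf:.4f}   converged: {self.converged}"
            f"   iterations: {self.n_iter}",
            "-" * 60,
            "variance components:",
        ]
        for k, v in self.components.items():
            se = (
                f" ({self.component_se[k]:.4f})"
                if self.component_se and k in self.component_se
                else ""
            )
            fx = "  [fixed]" if k in m.fixed_components else ""
            lines.append(f"  {k:<14}{v: .4f}{se}{fx}")
        r = self.ratios()
        lines.append(
            "  h2 = {h2:.3f}{h2se}   m2 = {m2:.3f}{m2se}".format(
                h2=r["h2"],
                h2se=f" ({r['h2_se']:.3f})" if "h2_se" in r else "",
                m2=r.get("m2", 0.0),
                m2se=f" ({r['m2_se']:.3f})" if "m2_se" in r else "",
            )
        )
        for fl in self.boundary_flags:
            lines.append(f"  ! {fl}")
        lines.append("-" * 60)
        lines.append("fixed effects (first %d):" % max_fe)
        fe = self.fe_params
        bse = self.bse
        shown = [n for n in fe.index if not n.startswith("plate[")][:max_fe]
        for nme in shown:
            lines.append(f"  {nme:<24}{fe[nme]: .4f} ({bse[nme]:.4f})")
        hidden = len(fe) - len(shown)
        if hidden > 0:
            lines.append(f"  ... {hidden} plate coefficients not shown")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# module-level inference helpers
# ---------------------------------------------------------------------------

def lrt(llf_full: float, llf_reduced: float, df: int) -> dict:
    """Likelihood-ratio test LR = 2 (logL_full - logL_reduced).

    The statistic is clipped at zero and referred to a plain chi-square with
    ``df`` degrees of freedom (no boundary mixture).
    """
    if df <= 0:
        raise ValueError("df must be positive")
    stat = max(0.0, 2.0 * (llf_full - llf_reduced))
    return {"statistic": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}


def ratios(components, cov: pd.DataFrame | None = None) -> dict:
    """Heritability h2 = s2_A / (s2_A + s2_m + s2_e) and maternal ratio m2.

    The denominator is the phenotypic variance of the animal model (plate
    variance, when fitted random, is excluded, matching how the study defines
    the ratios).  Delta-method SEs are added when a component covariance
    matrix is supplied.
    """
    sa = components["sigma2_A"]
    sm = components.get("sigma2_m", 0.0)
    se_ = components["sigma2_e"]
    tot = sa + sm + se_
    if tot <= 0:
        raise ValueError("zero total variance")
    out = {"h2": sa / tot, "sigma2_P": tot}
    if "sigma2_m" in components:
        out["m2"] = sm / tot
    if cov is not None:
        names = list(cov.index)
        V = cov.to_numpy()

        def dm(grads: dict) -> float:
            g = np.array([grads.get(nm, 0.0) for nm in names])
            return float(np.sqrt(max(0.0, g @ V @ g)))

        out["h2_se"] = dm(
            {
                "sigma2_A": (tot - sa) / tot**2,
                "sigma2_m": -sa / tot**2,
                "sigma2_e": -sa / tot**2,
            }
        )
        if "m2" in out:
            out["m2_se"] = dm(
                {
                    "sigma2_A": -sm / tot**2,
                    "sigma2_m": (tot - sm) / tot**2,
                    "sigma2_e": -sm / tot**2,
                }
            )
    return out


def genetic_trend(results: AnimalModelResults, ped: Pedigree | None = None) -> pd.DataFrame:
    """Mean EBV per line x generation, in titer points and in sigma_A units."""
    ped = ped or results.model.ped
    ebv = results.ebv.to_numpy()
    df = pd.DataFrame(
        {"line": ped.line, "generation": ped.generation, "ebv": ebv}
    )
    df = df[df["generation"] >= 0]
    out = (
        df.groupby(["line", "generation"], sort=True)["ebv"]
        .agg(mean_ebv="mean", n="size")
        .reset_index()
    )
    sig_a = results.sigma_a
    out["mean_ebv_sigma_a"] = out["mean_ebv"] / sig_a if sig_a > 0 else np.nan
    return out
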