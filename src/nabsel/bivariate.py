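"""Bivariate animal-model REML: genetic, maternal and residual correlations.

Two traits are analysed jointly with trait-specific fixed effects, additive
genetic effects with covariance ``G_A (x) A`` (Kronecker with the numerator
relationship matrix), maternal environmental effects with ``G_M (x) I`` over
dam groups, and per-animal 2x2 residual covariance for animals recorded on
both traits.  The sex-split mode treats one trait measured in males and
females as two traits; each animal then contributes one record and the
residual covariance is inestimable and fixed at zero.

The restricted likelihood is maximised over log variance ratios and
tanh-bounded correlations with the overall residual scale profiled out; the
additive correlation can be held fixed (e.g. at 0.999 for the likelihood-
ratio test that r_a = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

from .model import ConvergenceWarning, _splu_spd, build_fixed_design
from .pedigree import Pedigree, a_inverse

__all__ = ["BivariateAnimalModel", "BivariateResults"]


def _embed(mat, row_off, col_off, size):
    coo = mat.tocoo()
    return sparse.coo_matrix(
        (coo.data, (coo.row + row_off, coo.col + col_off)), shape=(size, size)
    ).tocsc()


class BivariateAnimalModel:
    """Two-trait animal model with maternal environmental effects.

    Parameters
    ----------
    data : DataFrame
        One row per animal; the two trait columns may contain NaN for
        record-wise missingness.
    pedigree : Pedigree
    traits : (str, str)
        The two response columns.
    fixed : sequence of str
        Fixed factor terms, built separately within each trait.
    residual_cov : {'free', 'zero'}
        Whether the residual covariance between traits on the same animal is
        estimated or fixed at 0 (forced to 'zero' when no animal carries
        both traits, as in the sex-split analysis).
    fix_ra : float, optional
        Hold the additive genetic correlation at this value.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        pedigree: Pedigree,
        traits: tuple,
        fixed=("plate",),
        maternal_env: bool = True,
        residual_cov: str = "free",
        fix_ra: float | None = None,
        maternal_group: str | None = None,
    ):
        if len(traits) != 2:
            raise ValueError("exactly two traits required")
        self.traits = tuple(traits)
        obs = [data[t].notna().to_numpy() for t in traits]
        if not all(o.any() for o in obs):
            raise ValueError("each trait needs at least one observation")
        self.ped = pedigree
        self.maternal_env = maternal_env
        self.fix_ra = fix_ra

        n_ped = pedigree.n
        mg_col = maternal_group or ("dam_group" if "dam_group" in data else "dam")

        # stacked records: trait 0 block then trait 1 block
        recs = []
        Xs, fe_names = [], []
        for t_ix, t in enumerate(traits):
            sub = data.loc[obs[t_ix]].reset_index(drop=True)
            X, names, _ = build_fixed_design(sub, fixed)
            Xs.append(X)
            fe_names.extend([f"{t}:{nm}" for nm in names])
            recs.append(sub)
        self.fe_names = fe_names
        n0, n1 = len(recs[0]), len(recs[1])
        self.nobs = n0 + n1
        self.p = Xs[0].shape[1] + Xs[1].shape[1]
        y = np.concatenate([recs[0][traits[0]].to_numpy(float),
                            recs[1][traits[1]].to_numpy(float)])
        self.y = y

        # residual pairing: records of the same animal on both traits
        a0 = recs[0]["animal"].astype(str).to_numpy()
        a1 = recs[1]["animal"].astype(str).to_numpy()
        pos1 = {a: k for k, a in enumerate(a1)}
        pair0, pair1 = [], []
        for k, a in enumerate(a0):
            j = pos1.get(a)
            if j is not None:
                pair0.append(k)
                pair1.append(j)
        pair0 = np.asarray(pair0, dtype=np.int64)
        pair1 = np.asarray(pair1, dtype=np.int64) + n0
        self.n_pair = pair0.size
        single0 = np.setdiff1d(np.arange(n0), pair0)
        single1 = np.setdiff1d(np.arange(n0, self.nobs), pair1)
        self.n_single = (single0.size, single1.size)
        if self.n_pair == 0:
            residual_cov = "zero"
        self.residual_cov = residual_cov

        # design: X blockdiag | additive (2 n_ped) | maternal (2 n_dam)
        Xbd = sparse.block_diag(
            [sparse.csr_matrix(Xs[0]), sparse.csr_matrix(Xs[1])]
        ).tocsr()
        off = self.p
        self._off_a = off
        cols_a = np.concatenate(
            [pedigree.indices(a0), pedigree.indices(a1) + n_ped]
        )
        Za = sparse.coo_matrix(
            (np.ones(self.nobs), (np.arange(self.nobs), cols_a)),
            shape=(self.nobs, 2 * n_ped),
        ).tocsr()
        blocks = [Xbd, Za]
        off += 2 * n_ped
        self._off_m = None
        self.n_dam = 0
        if maternal_env:
            grp = pd.concat(
                [recs[0][mg_col].astype(str), recs[1][mg_col].astype(str)],
                ignore_index=True,
            )
            codes, levels = pd.factorize(grp, sort=True)
            self.n_dam = len(levels)
            cols_m = codes + np.where(np.arange(self.nobs) < n0, 0, self.n_dam)
            Zm = sparse.coo_matrix(
                (np.ones(self.nobs), (np.arange(self.nobs), cols_m)),
                shape=(self.nobs, 2 * self.n_dam),
            ).tocsr()
            blocks.append(Zm)
            self._off_m = off
            off += 2 * self.n_dam
        self._m = off
        W = sparse.hstack(blocks).tocsr()
        self._logdet_xtx = sum(
            float(np.linalg.slogdet(Xt.T @ Xt)[1]) for Xt in Xs
        )

        # residual patterns: diag/cross masks as sparse weights on records
        n_rec = self.nobs
        def diag_pattern(ix):
            return sparse.coo_matrix(
                (np.ones(ix.size), (ix, ix)), shape=(n_rec, n_rec)
            ).tocsr()

        patterns = {
            "d0p": diag_pattern(pair0),
            "d1p": diag_pattern(pair1),
            "d0s": diag_pattern(single0),
            "d1s": diag_pattern(single1),
        }
        cross = sparse.coo_matrix(
            (np.ones(self.n_pair), (pair0, pair1)), shape=(n_rec, n_rec)
        )
        patterns["x"] = (cross + cross.T).tocsr()

        self._WtMW = {}
        self._WtMy = {}
        self._yMy = {}
        for k, Mk in patterns.items():
            MW = Mk @ W
            self._WtMW[k] = (W.T @ MW).tocsc()
            self._WtMy[k] = np.asarray(W.T @ (Mk @ y)).ravel()
            self._yMy[k] = float(y @ (Mk @ y))

        Ainv = a_inverse(pedigree)
        self._logdet_a = pedigree.log_det_a()
        M = self._m
        self._P_a00 = _embed(Ainv, self._off_a, self._off_a, M)
        self._P_a11 = _embed(Ainv, self._off_a + n_ped, self._off_a + n_ped, M)
        c = _embed(Ainv, self._off_a, self._off_a + n_ped, M)
        self._P_a01 = (c + c.T).tocsc()
        if maternal_env:
            eye = sparse.identity(self.n_dam, format="coo")
            self._P_m00 = _embed(eye, self._off_m, self._off_m, M)
            self._P_m11 = _embed(
                eye, self._off_m + self.n_dam, self._off_m + self.n_dam, M
            )
            cm = _embed(eye, self._off_m, self._off_m + self.n_dam, M)
            self._P_m01 = (cm + cm.T).tocsc()

        self._data_cols = {"n0": n0, "n1": n1}
        self._trait_frames = recs
        self._fixed_terms = tuple(fixed)
        self._mg_col = mg_col

    # -- likelihood --------------------------------------------------------

    def _evaluate(self, par: dict, profile: bool = True):
        """Restricted log-likelihood at one parameter point.

        ``par`` carries variances ``la1, la2, lm1, lm2`` and the trait-2
        residual ``k_e2`` either as ratios to the trait-1 residual variance
        (``profile=True``; that residual is then estimated in closed form) or
        as absolute values together with ``sigma2_e1`` (``profile=False``).
        """
        v1 = 1.0 if profile else par["sigma2_e1"]
        v2 = par["k_e2"] * (1.0 if profile else 1.0)
        if not profile:
            v2 = par["sigma2_e2"]
        re = par["r_e"]
        la1, la2, ra = par["la1"], par["la2"], par["r_a"]
        lm1, lm2, rm = par.get("lm1", 0.0), par.get("lm2", 0.0), par.get("r_m", 0.0)

        # residual inverse weights per record pattern
        det = v1 * v2 * (1.0 - re * re)
        if det <= 0:
            return None
        w = {
            "d0p": v2 / det,
            "d1p": v1 / det,
            "x": -re * np.sqrt(v1 * v2) / det,
            "d0s": 1.0 / v1,
            "d1s": 1.0 / v2,
        }

        C = None
        rhs = 0.0
        yry = 0.0
        for k in self._WtMW:
            if w[k] == 0.0:
                continue
            term = w[k] * self._WtMW[k]
            C = term if C is None else C + term
            rhs = rhs + w[k] * self._WtMy[k]
            yry = yry + w[k] * self._yMy[k]

        # additive precision
        ca = ra * np.sqrt(la1 * la2)
        det_a = la1 * la2 - ca * ca
        if det_a <= 0 or la1 <= 0 or la2 <= 0:
            return None
        C = C + (la2 / det_a) * self._P_a00 + (la1 / det_a) * self._P_a11 \
            - (ca / det_a) * self._P_a01
        n_ped = self.ped.n
        log_g = n_ped * np.log(det_a) + 2.0 * self._logdet_a
        if self.maternal_env:
            cm = rm * np.sqrt(lm1 * lm2)
            det_m = lm1 * lm2 - cm * cm
            if det_m <= 0 or lm1 <= 0 or lm2 <= 0:
                return None
            C = C + (lm2 / det_m) * self._P_m00 + (lm1 / det_m) * self._P_m11 \
                - (cm / det_m) * self._P_m01
            log_g += self.n_dam * np.log(det_m)

        lu = _splu_spd(C.tocsc())
        theta = lu.solve(rhs)
        ypy = yry - float(theta @ rhs)
        logdet_c = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        log_r = (
            self.n_pair * np.log(v1 * v2 * (1 - re * re))
            + self.n_single[0] * np.log(v1)
            + self.n_single[1] * np.log(v2)
        )
        np_ = self.nobs - self.p
        if profile:
            s = ypy / np_
            quad = np_
            extra = np_ * np.log(s)
        else:
            s = 1.0
            quad = ypy
            extra = 0.0
        if profile and s <= 0:
            return None
        m2ll = (
            np_ * np.log(2 * np.pi) + extra + log_r + log_g + logdet_c + quad
            - self._logdet_xtx
        )
        return {"llf": -0.5 * m2ll, "scale": s, "theta": theta, "lu": lu}

    def loglike(self, components: dict) -> float:
        """Restricted log-likelihood at absolute components.

        Keys: ``sigma2_A1, sigma2_A2, r_a, sigma2_m1, sigma2_m2, r_m,
        sigma2_e1, sigma2_e2, r_e``.
        """
        ev = self._evaluate(
            {
                "la1": components["sigma2_A1"],
                "la2": components["sigma2_A2"],
                "r_a": components["r_a"],
                "lm1": components.get("sigma2_m1", 0.0),
                "lm2": components.get("sigma2_m2", 0.0),
                "r_m": components.get("r_m", 0.0),
                "k_e2": components["sigma2_e2"],
                "r_e": components.get("r_e", 0.0),
                "sigma2_e1": components["sigma2_e1"],
                "sigma2_e2": components["sigma2_e2"],
            },
            profile=False,
        )
        return -np.inf if ev is None else ev["llf"]

    # -- fitting -----------------------------------------------------------

    def _univariate_start(self) -> dict:
        """Variance-ratio starting values from per-trait univariate REML fits."""
        from .model import AnimalModel

        lam = {}
        for t_ix, t in enumerate(self.traits):
            m = AnimalModel(
                self._trait_frames[t_ix],
                self.ped,
                t,
                fixed=self._fixed_terms,
                maternal_env=self.maternal_env,
                maternal_group=self._mg_col if self.maternal_env else None,
            )
            r = m.fit(se=False)
            c = r.components
            lam[t_ix] = c
        s2e1 = lam[0]["sigma2_e"]
        out = {
            "la1": lam[0]["sigma2_A"] / s2e1,
            "la2": lam[1]["sigma2_A"] / s2e1,
            "k_e2": lam[1]["sigma2_e"] / s2e1,
        }
        if self.maternal_env:
            out["lm1"] = lam[0]["sigma2_m"] / s2e1
            out["lm2"] = lam[1]["sigma2_m"] / s2e1
        return out

    def fit(
        self,
        start: dict | None = None,
        maxfev: int = 2000,
        polish_iter: int = 40,
    ) -> "BivariateResults":
        """Maximise the restricted likelihood and return the fitted results.

        Optimisation is staged for speed: per-trait univariate REML fits seed
        the variance ratios, a short derivative-free search sets the three
        correlations at those variances, and a bounded quasi-Newton pass then
        polishes all free parameters jointly.
        """
        free_rm = self.maternal_env
        free_re = self.residual_cov == "free"
        free_ra = self.fix_ra is None

        s = dict(start or {})
        if not {"la1", "la2", "k_e2"} <= s.keys():
            s = {**self._univariate_start(), **s}

        names = ["la1", "la2"]
        x0 = [np.log(s.get("la1", 0.4)), np.log(s.get("la2", 0.4))]
        if free_ra:
            names.append("r_a")
            x0.append(np.arctanh(np.clip(s.get("r_a", 0.5), -0.97, 0.97)))
        if self.maternal_env:
            names += ["lm1", "lm2"]
            x0 += [np.log(max(s.get("lm1", 0.06), 1e-4)),
                   np.log(max(s.get("lm2", 0.06), 1e-4))]
            if free_rm:
                names.append("r_m")
                x0.append(np.arctanh(np.clip(s.get("r_m", 0.3), -0.97, 0.97)))
        names.append("k_e2")
        x0.append(np.log(s.get("k_e2", 1.0)))
        if free_re:
            names.append("r_e")
            x0.append(np.arctanh(np.clip(s.get("r_e", 0.3), -0.97, 0.97)))
        x0 = np.asarray(x0)
        corr_ix = [k for k, nm in enumerate(names) if nm in ("r_a", "r_m", "r_e")]

        def unpack(x):
            vals = dict(zip(names, x))
            par = {
                "la1": np.exp(vals["la1"]),
                "la2": np.exp(vals["la2"]),
                "r_a": np.tanh(vals["r_a"]) if free_ra else float(self.fix_ra),
                "k_e2": np.exp(vals["k_e2"]),
                "r_e": np.tanh(vals["r_e"]) if free_re else 0.0,
            }
            if self.maternal_env:
                par["lm1"] = np.exp(vals["lm1"])
                par["lm2"] = np.exp(vals["lm2"])
                par["r_m"] = np.tanh(vals["r_m"]) if free_rm else 0.0
            return par

        n_eval = [0]

        def objective(x):
            n_eval[0] += 1
            ev = self._evaluate(unpack(x), profile=True)
            return 1e12 if ev is None else -ev["llf"]

        zmax = 3.8  # |r| <= 0.9989
        bounds = [
            (-zmax, zmax) if nm in ("r_a", "r_m", "r_e") else (-12.0, 6.0)
            for nm in names
        ]

        def lbfgs(x, maxfun, gtol):
            return optimize.minimize(
                objective,
                x,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": polish_iter,
                    "maxfun": maxfun,
                    "ftol": 1e-10,
                    "gtol": gtol,
                    "eps": 1e-5,
                },
            )

        def refine_correlations(x):
            # correlations sit in flat likelihood directions; a bounded 1-D
            # search per coordinate pins each down far more cheaply than the
            # joint quasi-Newton pass does
            x = x.copy()
            for k in corr_ix:
                def obj_k(z, k=k):
                    xk = x.copy()
                    xk[k] = z
                    return objective(xk)

                res_k = optimize.minimize_scalar(
                    obj_k,
                    bounds=(-zmax, zmax),
                    method="bounded",
                    options={"xatol": 5e-4},
                )
                x[k] = res_k.x
            return x

        # rough joint pass, precise correlation refinement, joint re-polish
        res = lbfgs(x0, maxfun=min(maxfev, 130), gtol=1e-3)
        x = refine_correlations(res.x)
        res = lbfgs(x, maxfun=min(maxfev, 70), gtol=2e-4)
        x = refine_correlations(res.x) if corr_ix else res.x
        final = optimize.OptimizeResult(
            x=x, fun=objective(x), success=True, status=0, nit=n_eval[0]
        )
        res = final
        converged = np.isfinite(res.fun)
        if not converged:
            warnings.warn("bivariate REML did not converge", ConvergenceWarning)
        par = unpack(res.x)
        ev = self._evaluate(par, profile=True)
        scale = ev["scale"]
        t1, t2 = self.traits
        comp = {
            "sigma2_A1": par["la1"] * scale,
            "sigma2_A2": par["la2"] * scale,
            "r_a": par["r_a"],
            "sigma2_e1": scale,
            "sigma2_e2": par["k_e2"] * scale,
            "r_e": par["r_e"],
        }
        if self.maternal_env:
            comp["sigma2_m1"] = par["lm1"] * scale
            comp["sigma2_m2"] = par["lm2"] * scale
            comp["r_m"] = par["r_m"]
        flags = []
        for key in ("r_a", "r_m", "r_e"):
            if key in comp and abs(comp[key]) > 0.99 and (key != "r_a" or free_ra):
                flags.append(f"{key} at the boundary of the parameter space")
        return BivariateResults(
            model=self,
            components=comp,
            llf=float(ev["llf"]),
            converged=bool(res.success),
            n_iter=int(res.nit),
            boundary_flags=flags,
            _theta=ev["theta"],
        )

    @classmethod
    def from_sex_split(
        cls,
        data: pd.DataFrame,
        pedigree: Pedigree,
        response: str,
        fixed=("plate",),
        **kwargs,
    ) -> "BivariateAnimalModel":
        """Treat male and female titers of one trait as two traits.

        Each animal contributes exactly one record, so the residual
        covariance is fixed at zero.
        """
        df = data.copy()
        df[f"{response}_M"] = df[response].where(df["sex"] == "M")
        df[f"{response}_F"] = df[response].where(df["sex"] == "F")
        return cls(
            df,
            pedigree,
            traits=(f"{response}_M", f"{response}_F"),
            fixed=fixed,
            residual_cov="zero",
            **kwargs,
        )


@dataclass
class BivariateResults:
    """Fitted two-trait animal model."""

    model: BivariateAnimalModel
    components: dict
    llf: float
    converged: bool
    n_iter: int
    boundary_flags: list = field(default_factory=list)
    _theta: np.ndarray | None = None

    @property
    def r_a(self) -> float:
        return self.components["r_a"]

    @property
    def r_m(self) -> float | None:
        return self.components.get("r_m")

    @property
    def r_e(self) -> float:
        return self.components.get("r_e", 0.0)

    @property
    def r_p(self) -> float:
        """Phenotypic correlation implied by the component covariances."""
        c = self.components
        cov = (
            c["r_a"] * np.sqrt(c["sigma2_A1"] * c["sigma2_A2"])
            + c.get("r_m", 0.0)
            * np.sqrt(c.get("sigma2_m1", 0.0) * c.get("sigma2_m2", 0.0))
            + c.get("r_e", 0.0) * np.sqrt(c["sigma2_e1"] * c["sigma2_e2"])
        )
        v1 = c["sigma2_A1"] + c.get("sigma2_m1", 0.0) + c["sigma2_e1"]
        v2 = c["sigma2_A2"] + c.get("sigma2_m2", 0.0) + c["sigma2_e2"]
        return float(cov / np.sqrt(v1 * v2))

    def trait_components(self, which: int) -> dict:
        i = which + 1
        c = self.components
        return {
            "sigma2_A": c[f"sigma2_A{i}"],
            "sigma2_m": c.get(f"sigma2_m{i}", 0.0),
            "sigma2_e": c[f"sigma2_e{i}"],
        }

    def h2(self, which: int) -> float:
        tc = self.trait_components(which)
        return tc["sigma2_A"] / sum(tc.values())

    def summary(self) -> str:
        m = self.model
        t1, t2 = m.traits
        lines = [
            "Bivariate animal model REML fit",
            "=" * 60,
            f"traits: {t1} / {t2}   records: {m.nobs} "
            f"({m.n_pair} animals on both)",
            f"restricted logL: {self.llf:.4f}   converged: {self.converged}",
            "-" * 60,
        ]
        for i, t in enumerate((t1, t2)):
            tc = self.trait_components(i)
            lines.append(
                f"  {t:<10} s2_A={tc['sigma2_A']:.4f}  s2_m={tc['sigma2_m']:.4f}"
                f"  s2_e={tc['sigma2_e']:.4f}  h2={self.h2(i):.3f}"
            )
        lines.append(
            f"  r_a={self.r_a:.3f}  "
            + (f"r_m={self.r_m:.3f}  " if self.r_m is not None else "")
            + f"r_e={self.r_e:.3f}  r_p={self.r_p:.3f}"
        )
        for fl in self.boundary_flags:
            lines.append(f"  ! {fl}")
        return "\n".join(lines)
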