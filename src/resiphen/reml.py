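"""Variance components, heritabilities and breeding values by REML.

The animal model is ``y = Xb + Za + Wc + e`` with fixed effects b (sex,
farm, covariate maximum age), additive genetic effects
``a ~ N(0, K σ²_a)`` for a pedigree (A), genomic (G) or combined (H)
relationship matrix K, random contemporary-group effects
``c ~ N(0, I σ²_c)`` and residuals ``e ~ N(0, I σ²_e)``. Heritability is
``h² = σ²_a / (σ²_a + σ²_c + σ²_e)`` and the common-environment proportion
``c² = σ²_c / total``. Bivariate models stack two such models with a full
2×2 additive and contemporary-group covariance and a diagonal residual
covariance (records of the two traits are treated as independent given the
random effects), yielding the genetic correlation
``r_g = σ_a1,a2 / (σ_a1 σ_a2)``.

Estimation is restricted maximum likelihood on the mixed-model equations:
EM updates guarantee a non-decreasing restricted likelihood; an
average-information (AI) step is attempted each round and kept when it
stays in the parameter space and improves the likelihood, giving fast
terminal convergence. Standard errors come from the inverse AI matrix at
convergence; h², c² and r_g standard errors by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

__all__ = [
    "VarianceComponents",
    "BivariateComponents",
    "make_contemporary_groups",
    "fit_univariate",
    "fit_bivariate",
    "solve_blup",
    "gcv",
    "restricted_loglik_direct",
]


# ---------------------------------------------------------------------------
# model assembly helpers


def make_contemporary_groups(
    meta: pd.DataFrame,
    cols: tuple = ("farm", "compartment", "entry_date"),
    min_size: int = 10,
) -> pd.Series:
    """Contemporary-group labels: column combination, small groups merged.

    Groups with fewer than ``min_size`` animals are pooled into a single
    remainder level, mirroring routine genetic-evaluation practice.
    """
    key = meta[list(cols)].astype(str).agg("|".join, axis=1)
    sizes = key.value_counts()
    small = sizes.index[sizes < min_size]
    out = key.where(~key.isin(small), other="_remainder")
    return out.rename("cg")


def _design_fixed(df: pd.DataFrame, fixed, covariates) -> np.ndarray:
    cols = [np.ones(len(df))]
    for f in fixed or ():
        if f not in df.columns:
            continue
        dummies = pd.get_dummies(df[f].astype(str), drop_first=True, dtype=float)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy())
    for c in covariates or ():
        if c not in df.columns:
            continue
        x = df[c].to_numpy(dtype=float)
        if np.nanstd(x) == 0:
            warnings.warn(f"covariate {c!r} has zero variance; dropped")
            continue
        cols.append(x - np.nanmean(x))
    X = np.column_stack(cols)
    # guard against rank deficiency (e.g. a factor confounded with intercept)
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-8 * np.abs(np.diag(r)).max()
    return X[:, keep]


@dataclass
class _Term:
    """One random effect across traits: covariance Gamma (t x t) ⊗ K (q x q)."""

    name: str
    q: int
    kinv: np.ndarray  # dense q x q
    kinv_sp: sparse.csr_matrix
    logdet_k: float
    level_ids: list
    maps: list  # per trait: record -> level index array


class _MixedModel:
    """Dense mixed-model-equation engine for 1 or 2 traits."""

    def __init__(self, ys, Xs, terms: list[_Term]):
        self.T = len(ys)
        self.ys = [np.asarray(y, dtype=float) for y in ys]
        self.Xs = [np.asarray(X, dtype=float) for X in Xs]
        self.terms = terms
        self.n = [len(y) for y in self.ys]
        self.p = [X.shape[1] for X in self.Xs]

        # solution layout: fixed blocks per trait, then per term per trait
        offset = 0
        self.fixed_slices = []
        for t in range(self.T):
            self.fixed_slices.append(slice(offset, offset + self.p[t]))
            offset += self.p[t]
        self.term_slices = []  # [term][trait]
        for term in terms:
            per_trait = []
            for t in range(self.T):
                per_trait.append(slice(offset, offset + term.q))
                offset += term.q
            self.term_slices.append(per_trait)
        self.m = offset

        # per-trait design cross-products (theta-independent)
        self.S = []
        self.Ty = []
        self.yy = []
        self.Tmats = []
        for t in range(self.T):
            # horizontally concatenate zero-padded blocks in global column order
            parts = []
            for tt in range(self.T):
                if tt == t:
                    parts.append(sparse.csr_matrix(self.Xs[t]))
                else:
                    parts.append(sparse.csr_matrix((self.n[t], self.p[tt])))
            for term in terms:
                z = term.maps[t]
                ind = sparse.csr_matrix(
                    (np.ones(len(z)), (np.arange(len(z)), z)), shape=(self.n[t], term.q)
                )
                for tt in range(self.T):
                    if tt == t:
                        parts.append(ind)
                    else:
                        parts.append(sparse.csr_matrix((self.n[t], term.q)))
            Tt = sparse.hstack(parts, format="csr")
            self.Tmats.append(Tt)
            self.S.append((Tt.T @ Tt).tocsr())
            self.Ty.append(Tt.T @ self.ys[t])
            self.yy.append(float(self.ys[t] @ self.ys[t]))
        self.T_all = sparse.vstack(self.Tmats).tocsr()
        self.y_all = np.concatenate(self.ys)
        self.trait_of_record = np.concatenate(
            [np.full(self.n[t], t) for t in range(self.T)]
        )

    # -- assembly -----------------------------------------------------------

    def _assemble(self, gammas, sig_e):
        M = (sum(self.S[t] / sig_e[t] for t in range(self.T))).toarray()
        rhs = np.zeros(self.m)
        for t in range(self.T):
            rhs += self.Ty[t] / sig_e[t]
        for r, term in enumerate(self.terms):
            gi = np.linalg.inv(np.atleast_2d(gammas[r]))
            for i in range(self.T):
                for j in range(self.T):
                    if gi[i, j] != 0.0:
                        M[self.term_slices[r][i], self.term_slices[r][j]] += gi[i, j] * term.kinv
        return M, rhs

    def _solve(self, gammas, sig_e):
        M, rhs = self._assemble(gammas, sig_e)
        cf = linalg.cho_factor(M, lower=True, check_finite=False)
        sol = linalg.cho_solve(cf, rhs, check_finite=False)
        logdet_m = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return M, rhs, cf, sol, logdet_m

    def _inverse(self, cf):
        C, info = linalg.lapack.dpotri(cf[0], lower=True)
        if info != 0:
            raise np.linalg.LinAlgError("MME inverse failed")
        C = np.tril(C) + np.tril(C, -1).T
        return C

    # -- likelihood ---------------------------------------------------------

    def loglik(self, gammas, sig_e, sol, rhs, logdet_m):
        ypy = sum(self.yy[t] / sig_e[t] for t in range(self.T)) - float(rhs @ sol)
        val = -0.5 * (logdet_m + ypy)
        for t in range(self.T):
            val -= 0.5 * self.n[t] * np.log(sig_e[t])
        for r, term in enumerate(self.terms):
            g = np.atleast_2d(gammas[r])
            val -= 0.5 * (term.q * np.linalg.slogdet(g)[1] + g.shape[0] * term.logdet_k)
        return float(val)

    # -- parameter vector helpers ------------------------------------------

    def _pack(self, gammas, sig_e):
        theta = []
        for g in gammas:
            g = np.atleast_2d(g)
            for i in range(self.T):
                for j in range(i, self.T):
                    theta.append(g[i, j])
        theta.extend(sig_e)
        return np.array(theta)

    def _unpack(self, theta):
        gammas = []
        pos = 0
        npair = self.T * (self.T + 1) // 2
        for _ in self.terms:
            g = np.zeros((self.T, self.T))
            for i in range(self.T):
                for j in range(i, self.T):
                    g[i, j] = g[j, i] = theta[pos]
                    pos += 1
            gammas.append(g)
        sig_e = list(theta[pos : pos + self.T])
        return gammas, sig_e

    # -- EM and AI steps ----------------------------------------------------

    def _traces(self, C):
        """tr(K⁻¹ C^{(r,i),(r,j)}) for every term and trait pair, and tr(C S_t)."""
        term_tr = []
        for r, term in enumerate(self.terms):
            Tm = np.zeros((self.T, self.T))
            for i in range(self.T):
                for j in range(i, self.T):
                    block = C[self.term_slices[r][i], self.term_slices[r][j]]
                    Tm[i, j] = Tm[j, i] = float(np.sum(term.kinv * block))
            term_tr.append(Tm)
        s_tr = [float(self.S[t].multiply(C).sum()) for t in range(self.T)]
        return term_tr, s_tr

    def _em_update(self, gammas, sig_e, sol, C):
        term_tr, s_tr = self._traces(C)
        new_g = []
        for r, term in enumerate(self.terms):
            g = np.zeros((self.T, self.T))
            us = [sol[self.term_slices[r][t]] for t in range(self.T)]
            for i in range(self.T):
                for j in range(i, self.T):
                    quad = float(us[i] @ (term.kinv_sp @ us[j]))
                    g[i, j] = g[j, i] = (quad + term_tr[r][i, j]) / term.q
            new_g.append(g)
        new_e = []
        for t in range(self.T):
            e = self.ys[t] - self.Tmats[t] @ sol
            new_e.append((float(e @ e) + s_tr[t]) / self.n[t])
        return new_g, new_e

    def _score_ai(self, gammas, sig_e, sol, C, cf):
        """Gradient of the restricted log-likelihood and AI matrix."""
        term_tr, s_tr = self._traces(C)
        resid = self.y_all - self.T_all @ sol
        rinv = np.concatenate(
            [np.full(self.n[t], 1.0 / sig_e[t]) for t in range(self.T)]
        )
        Py = rinv * resid

        fvecs = []
        labels = []
        for r, term in enumerate(self.terms):
            g = np.atleast_2d(gammas[r])
            gi = np.linalg.inv(g)
            us = np.column_stack([sol[self.term_slices[r][t]] for t in range(self.T)])
            for i in range(self.T):
                for j in range(i, self.T):
                    E = np.zeros((self.T, self.T))
                    E[i, j] = E[j, i] = 1.0
                    wmat = us @ (gi @ E)  # = us @ (E @ gi).T; column t feeds trait t
                    f = np.zeros(len(self.y_all))
                    offset = 0
                    for t in range(self.T):
                        z = term.maps[t]
                        f[offset : offset + self.n[t]] = wmat[z, t]
                        offset += self.n[t]
                    fvecs.append(f)
                    labels.append(("g", r, i, j, gi, E))
        for t in range(self.T):
            f = np.zeros(len(self.y_all))
            sel = self.trait_of_record == t
            f[sel] = Py[sel]
            fvecs.append(f)
            labels.append(("e", t))

        # scores
        score = []
        for lab, f in zip(labels, fvecs):
            ypvy = float(Py @ f)
            if lab[0] == "g":
                _, r, i, j, gi, E = lab
                term = self.terms[r]
                t1 = term.q * np.trace(E @ gi)
                inner = gi @ term_tr[r] @ gi
                t2 = float(np.sum(E * inner))
                tr_pv = t1 - t2
            else:
                t = lab[1]
                tr_pv = self.n[t] / sig_e[t] - s_tr[t] / sig_e[t] ** 2
                ypvy = ypvy  # f already = S_t Py, so Py@f = y'P S_t P y
            score.append(-0.5 * (tr_pv - ypvy))
        score = np.array(score)

        # AI matrix: 0.5 * f_i' P f_j with P f = R⁻¹(f − T M⁻¹ T' R⁻¹ f)
        F = np.column_stack(fvecs)
        RF = F * rinv[:, None]
        TtRF = self.T_all.T @ RF
        sol_f = linalg.cho_solve(cf, TtRF, check_finite=False)
        PF = rinv[:, None] * (F - self.T_all @ sol_f)
        AI = 0.5 * (F.T @ PF)
        return score, AI

    # -- main loop ----------------------------------------------------------

    def fit(self, gammas0, sig_e0, method="ai", tol=1e-8, max_iter=500, var_floor=None):
        gammas = [np.atleast_2d(np.array(g, dtype=float)) for g in gammas0]
        sig_e = [float(s) for s in sig_e0]
        vary = np.mean([np.var(y) for y in self.ys])
        floor = var_floor if var_floor is not None else 1e-10 * vary

        M, rhs, cf, sol, logdet_m = self._solve(gammas, sig_e)
        ll = self.loglik(gammas, sig_e, sol, rhs, logdet_m)
        ai_last = None
        converged = False
        history = [ll]
        for it in range(1, max_iter + 1):
            C = self._inverse(cf)
            theta_old = self._pack(gammas, sig_e)

            new_g = new_e = None
            pinned = np.zeros(len(theta_old), dtype=bool)
            if method == "ai":
                score, AI = self._score_ai(gammas, sig_e, sol, C, cf)
                ai_last = AI
                # active-set step: a variance at the zero boundary whose
                # gradient points outward stays pinned at the floor
                pinned = (theta_old <= 1.01 * floor) & (score < 0.0)
                active = ~pinned
                try:
                    delta = np.zeros(len(theta_old))
                    sub = AI[np.ix_(active, active)]
                    delta[active] = np.linalg.solve(
                        sub + 1e-12 * np.eye(active.sum()), score[active]
                    )
                    for frac in (1.0, 0.5, 0.1):
                        cand = theta_old + frac * delta
                        cand[pinned] = floor
                        cg, ce = self._unpack(cand)
                        cg = [self._floor_gamma(g, floor) for g in cg]
                        ce = [max(e, floor) for e in ce]
                        M2, rhs2, cf2, sol2, ld2 = self._solve(cg, ce)
                        ll2 = self.loglik(cg, ce, sol2, rhs2, ld2)
                        if np.isfinite(ll2) and ll2 >= ll - 1e-8:
                            new_g, new_e = cg, ce
                            cf, sol, rhs, logdet_m, ll = cf2, sol2, rhs2, ld2, ll2
                            break
                except np.linalg.LinAlgError:
                    pass
            if new_g is None:  # EM fallback (or method == 'em')
                new_g, new_e = self._em_update(gammas, sig_e, sol, C)
                theta_em = self._pack(new_g, new_e)
                theta_em[pinned] = floor  # EM must not lift boundary params
                new_g, new_e = self._unpack(theta_em)
                new_g = [self._floor_gamma(g, floor) for g in new_g]
                new_e = [max(e, floor) for e in new_e]
                M, rhs, cf, sol, logdet_m = self._solve(new_g, new_e)
                ll = self.loglik(new_g, new_e, sol, rhs, logdet_m)

            gammas, sig_e = new_g, new_e
            history.append(ll)
            theta = self._pack(gammas, sig_e)
            denom = np.maximum(np.abs(theta_old), floor)
            rel = np.abs(theta - theta_old) / denom
            rel[pinned] = 0.0
            if np.max(rel) < tol:
                converged = True
                break

        if method == "ai" and ai_last is None:
            C = self._inverse(cf)
            _, ai_last = self._score_ai(gammas, sig_e, sol, C, cf)
        elif method != "ai":
            C = self._inverse(cf)
            _, ai_last = self._score_ai(gammas, sig_e, sol, C, cf)
        return dict(
            gammas=gammas,
            sig_e=sig_e,
            sol=sol,
            loglik=ll,
            history=history,
            n_iter=it,
            converged=converged,
            ai=ai_last,
        )

    @staticmethod
    def _floor_gamma(g, floor):
        g = np.atleast_2d(np.array(g, dtype=float))
        for i in range(g.shape[0]):
            g[i, i] = max(g[i, i], floor)
        # project correlations into [-0.999, 0.999] to keep Gamma PD
        for i in range(g.shape[0]):
            for j in range(i + 1, g.shape[1]):
                lim = 0.999 * np.sqrt(g[i, i] * g[j, j])
                g[i, j] = g[j, i] = np.clip(g[i, j], -lim, lim)
        return g


# ---------------------------------------------------------------------------
# public results


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_c: float
    sigma2_e: float
    h2: float
    c2: float
    se: dict
    loglik: float
    n_iter: int
    converged: bool
    ebv: pd.Series
    cg_effects: pd.Series
    fixed_effects: np.ndarray
    history: list = field(default_factory=list, repr=False)
    _model_info: dict | None = field(default=None, repr=False)

    @property
    def total(self) -> float:
        return self.sigma2_a + self.sigma2_c + self.sigma2_e

    def adjusted_phenotypes(self) -> pd.Series:
        """y* = y − Xb̂ − Wĉ = â + ê for the fitted records."""
        info = self._model_info
        ystar = info["y"] - info["X"] @ self.fixed_effects
        if len(self.cg_effects):
            ystar = ystar - self.cg_effects.to_numpy()[info["cg_map"]]
        return pd.Series(ystar, index=info["animals"], name="ystar")


@dataclass
class BivariateComponents:
    G0: np.ndarray  # 2x2 additive covariance
    C0: np.ndarray  # 2x2 contemporary-group covariance
    sigma2_e: tuple
    r_g: float
    se: dict
    h2: tuple
    loglik: float
    n_iter: int
    converged: bool
    ebv: pd.DataFrame


# ---------------------------------------------------------------------------
# model building from data frames


def _prepare(data, response, kinv_ids, fixed, covariates, cg_col, animal_col):
    df = data.dropna(subset=[response]).copy()
    if df.empty:
        raise ValueError(f"no records for response {response!r}")
    id_index = {a: i for i, a in enumerate(kinv_ids)}
    missing = set(df[animal_col]) - set(id_index)
    if missing:
        raise ValueError(f"animals absent from relationship matrix: {sorted(missing)[:5]}")
    y = df[response].to_numpy(dtype=float)
    X = _design_fixed(df, fixed, covariates)
    amap = df[animal_col].map(id_index).to_numpy()
    if cg_col is not None and cg_col in df.columns:
        levels = pd.unique(df[cg_col])
        lut = {g: i for i, g in enumerate(levels)}
        cmap = df[cg_col].map(lut).to_numpy()
    else:
        levels, cmap = np.array([]), None
    return df, y, X, amap, cmap, list(levels)


def _kinv_terms(kinv, kinv_ids, logdet_k, amaps, cg_levels_list, cmaps, n_traits):
    kinv_dense = kinv.toarray() if sparse.issparse(kinv) else np.asarray(kinv, dtype=float)
    kinv_sp = sparse.csr_matrix(kinv_dense)
    terms = [
        _Term(
            name="additive",
            q=len(kinv_ids),
            kinv=kinv_dense,
            kinv_sp=kinv_sp,
            logdet_k=logdet_k,
            level_ids=list(kinv_ids),
            maps=amaps,
        )
    ]
    if cmaps[0] is not None:
        # shared contemporary-group level set across traits
        all_levels = []
        for lv in cg_levels_list:
            for g in lv:
                if g not in all_levels:
                    all_levels.append(g)
        lut = {g: i for i, g in enumerate(all_levels)}
        q = len(all_levels)
        remapped = []
        for t in range(n_traits):
            remapped.append(
                np.array([lut[cg_levels_list[t][i]] for i in cmaps[t]], dtype=int)
            )
        eye = np.eye(q)
        terms.append(
            _Term(
                name="cg",
                q=q,
                kinv=eye,
                kinv_sp=sparse.identity(q, format="csr"),
                logdet_k=0.0,
                level_ids=all_levels,
                maps=remapped,
            )
        )
    return terms


def _logdet_from_kinv(kinv) -> float:
    kd = kinv.toarray() if sparse.issparse(kinv) else np.asarray(kinv, dtype=float)
    sign, ld = np.linalg.slogdet(kd)
    if sign <= 0:
        raise np.linalg.LinAlgError("relationship inverse is not positive definite")
    return -ld


def fit_univariate(
    data: pd.DataFrame,
    response: str,
    kinv,
    kinv_ids,
    fixed=("sex", "farm"),
    covariates=("max_age",),
    cg_col: str | None = "cg",
    animal_col: str = "animal",
    method: str = "ai",
    tol: float = 1e-8,
    max_iter: int = 500,
    start: tuple | None = None,
) -> VarianceComponents:
    """Univariate animal-model REML fit.

    ``data`` has one row per phenotyped animal; ``kinv`` is the inverse
    relationship matrix over ``kinv_ids`` (every phenotyped animal must
    appear). Returns variance components, h², c², GCV-ready σ²_a, EBVs for
    every animal in ``kinv_ids`` and the restricted log-likelihood.
    """
    df, y, X, amap, cmap, cg_levels = _prepare(
        data, response, kinv_ids, fixed, covariates, cg_col, animal_col
    )
    logdet_k = _logdet_from_kinv(kinv)
    terms = _kinv_terms(kinv, kinv_ids, logdet_k, [amap], [cg_levels], [cmap], 1)
    model = _MixedModel([y], [X], terms)

    vy = np.var(y)
    if start is None:
        has_cg = len(terms) > 1
        g0 = [np.array([[0.3 * vy]])]
        if has_cg:
            g0.append(np.array([[0.1 * vy]]))
        e0 = [0.6 * vy]
    else:
        g0 = [np.atleast_2d(g) for g in start[0]]
        e0 = list(start[1])
    res = model.fit(g0, e0, method=method, tol=tol, max_iter=max_iter)

    s2a = float(res["gammas"][0][0, 0])
    s2c = float(res["gammas"][1][0, 0]) if len(terms) > 1 else 0.0
    s2e = float(res["sig_e"][0])
    total = s2a + s2c + s2e
    se = _univariate_se(res, len(terms) > 1, total)
    ebv = pd.Series(res["sol"][model.term_slices[0][0]], index=list(kinv_ids), name="ebv")
    if len(terms) > 1:
        cg_eff = pd.Series(res["sol"][model.term_slices[1][0]], index=terms[1].level_ids)
    else:
        cg_eff = pd.Series(dtype=float)
    return VarianceComponents(
        sigma2_a=s2a,
        sigma2_c=s2c,
        sigma2_e=s2e,
        h2=s2a / total,
        c2=s2c / total,
        se=se,
        loglik=res["loglik"],
        n_iter=res["n_iter"],
        converged=res["converged"],
        ebv=ebv,
        cg_effects=cg_eff,
        fixed_effects=res["sol"][model.fixed_slices[0]],
        history=res["history"],
        _model_info=dict(y=y, X=X, cg_map=cmap, animals=df[animal_col].to_numpy()),
    )


def _univariate_se(res, has_cg, total):
    se = {}
    try:
        cov = np.linalg.inv(res["ai"])
        names = ["sigma2_a"] + (["sigma2_c"] if has_cg else []) + ["sigma2_e"]
        for i, nm in enumerate(names):
            se[nm] = float(np.sqrt(max(cov[i, i], 0.0)))
        # delta method for h2 = s2a / total
        theta = np.array(
            [res["gammas"][0][0, 0]]
            + ([res["gammas"][1][0, 0]] if has_cg else [])
            + [res["sig_e"][0]]
        )
        g = np.full(len(theta), -theta[0] / total**2)
        g[0] += 1.0 / total
        se["h2"] = float(np.sqrt(max(g @ cov @ g, 0.0)))
    except np.linalg.LinAlgError:
        pass
    return se


def fit_bivariate(
    data1: pd.DataFrame,
    data2: pd.DataFrame,
    response1: str,
    response2: str,
    kinv,
    kinv_ids,
    fixed=("sex", "farm"),
    covariates=("max_age",),
    cg_col: str | None = "cg",
    animal_col: str = "animal",
    method: str = "ai",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BivariateComponents:
    """Bivariate animal-model REML with residual covariance fixed at zero.

    The two traits may be measured on overlapping or distinct animal sets;
    genetic and contemporary-group covariances are estimated, residual
    covariance is structurally zero.
    """
    df1, y1, X1, amap1, cmap1, lv1 = _prepare(
        data1, response1, kinv_ids, fixed, covariates, cg_col, animal_col
    )
    df2, y2, X2, amap2, cmap2, lv2 = _prepare(
        data2, response2, kinv_ids, fixed, covariates, cg_col, animal_col
    )
    if df1.empty or df2.empty:
        raise ValueError("both traits need records")
    logdet_k = _logdet_from_kinv(kinv)
    terms = _kinv_terms(kinv, kinv_ids, logdet_k, [amap1, amap2], [lv1, lv2], [cmap1, cmap2], 2)
    model = _MixedModel([y1, y2], [X1, X2], terms)

    v1, v2 = np.var(y1), np.var(y2)
    g0 = [np.diag([0.3 * v1, 0.3 * v2])]
    if len(terms) > 1:
        g0.append(np.diag([0.1 * v1, 0.1 * v2]))
    e0 = [0.6 * v1, 0.6 * v2]
    res = model.fit(g0, e0, method=method, tol=tol, max_iter=max_iter)

    G0 = res["gammas"][0]
    C0 = res["gammas"][1] if len(terms) > 1 else np.zeros((2, 2))
    se1, se2 = res["sig_e"]
    denom = np.sqrt(G0[0, 0] * G0[1, 1])
    rg = float(G0[0, 1] / denom) if denom > 0 else np.nan
    tot1 = G0[0, 0] + C0[0, 0] + se1
    tot2 = G0[1, 1] + C0[1, 1] + se2
    se = _bivariate_se(res, len(terms) > 1, G0)
    ebv = pd.DataFrame(
        {
            "ebv1": res["sol"][model.term_slices[0][0]],
            "ebv2": res["sol"][model.term_slices[0][1]],
        },
        index=list(kinv_ids),
    )
    return BivariateComponents(
        G0=G0,
        C0=C0,
        sigma2_e=(float(se1), float(se2)),
        r_g=rg,
        se=se,
        h2=(float(G0[0, 0] / tot1), float(G0[1, 1] / tot2)),
        loglik=res["loglik"],
        n_iter=res["n_iter"],
        converged=res["converged"],
        ebv=ebv,
    )


def _bivariate_se(res, has_cg, G0):
    se = {}
    try:
        cov = np.linalg.inv(res["ai"])
        # parameter order: g11, g12, g22, (c11, c12, c22), e1, e2
        se["sigma_a1a2"] = float(np.sqrt(max(cov[1, 1], 0.0)))
        a, cab, b = G0[0, 0], G0[0, 1], G0[1, 1]
        if a > 0 and b > 0:
            grad = np.zeros(cov.shape[0])
            s = np.sqrt(a * b)
            grad[0] = -0.5 * cab / (s * a)
            grad[1] = 1.0 / s
            grad[2] = -0.5 * cab / (s * b)
            se["r_g"] = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        pass
    return se


def solve_blup(
    data: pd.DataFrame,
    response: str,
    kinv,
    kinv_ids,
    varcomp: VarianceComponents,
    fixed=("sex", "farm"),
    covariates=("max_age",),
    cg_col: str | None = "cg",
    animal_col: str = "animal",
) -> pd.Series:
    """BLUP solve at fixed variance components; returns EBVs for all kinv_ids.

    Used by cross-validation: phenotypes of masked animals are simply absent
    from ``data`` and their EBVs are predicted through relationships.
    """
    df, y, X, amap, cmap, cg_levels = _prepare(
        data, response, kinv_ids, fixed, covariates, cg_col, animal_col
    )
    logdet_k = _logdet_from_kinv(kinv)
    terms = _kinv_terms(kinv, kinv_ids, logdet_k, [amap], [cg_levels], [cmap], 1)
    model = _MixedModel([y], [X], terms)
    gam = [np.array([[max(varcomp.sigma2_a, 1e-12)]])]
    if len(terms) > 1:
        gam.append(np.array([[max(varcomp.sigma2_c, 1e-12)]]))
    _, rhs, cf, sol, _ = model._solve(gam, [varcomp.sigma2_e])
    return pd.Series(sol[model.term_slices[0][0]], index=list(kinv_ids), name="ebv")


def gcv(sigma2_a: float, log_scale: bool = True, mean: float | None = None) -> float:
    """Genetic coefficient of variation.

    For ln-variance/ln-MSE traits (exponential model) GCV = sqrt(σ²_a), i.e.
    the additive genetic SD on the log scale; for linear-scale traits
    GCV = σ_a / mean.
    """
    if sigma2_a < 0:
        raise ValueError("sigma2_a must be non-negative")
    sa = float(np.sqrt(sigma2_a))
    if log_scale:
        return sa
    if mean is None or mean == 0:
        raise ValueError("linear-scale GCV needs a nonzero trait mean")
    return sa / abs(mean)


def restricted_loglik_direct(y, X, V) -> float:
    """Dense restricted log-likelihood −½(ln|V| + ln|X'V⁻¹X| + y'Py).

    Brute-force oracle for small problems; independent of the MME engine.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtVX) @ X.T @ Vi
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtVX)
    return float(-0.5 * (ldV + ldX + y @ P @ y))
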