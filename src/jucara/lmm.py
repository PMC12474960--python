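"""REML/BLUP linear mixed-model engine for germplasm trials.

Fits Gaussian mixed models of the form

    y = X b + Z u + e,   u ~ N(0, G),   e ~ N(0, R),

where G is block-diagonal over random terms — an IID genotype effect, an
optional IID elevation-class effect, and a genotype-by-evaluation-time effect
whose t×t among-time covariance may be IDV, DIAG, compound-symmetric (CS) or
unstructured (US) — and R is diagonal, either homogeneous or with a separate
variance per level of a grouping column (field sampling group or evaluation
time).

Estimation maximizes the restricted (REML) log-likelihood directly over
unconstrained transformed parameters (log variances; log-Cholesky factors for
US; a bounded correlation for CS), so nonnegativity and positive
semidefiniteness hold by construction and boundary estimates appear as
variances shrinking to zero. Each likelihood evaluation costs O(q^2) in the
number of random-effect levels: the per-residual-group Gram matrices of
[X Z y] are precomputed once, so no n×n matrix is ever formed.

BLUPs and the full prediction-error-variance (PEV) matrix come from the
inverse coefficient matrix of the mixed-model equations at the optimum, which
also feeds the generalized (Cullis) heritability and per-genotype prediction
accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

_LOG2PI = np.log(2.0 * np.pi)
_BOUND = 23.0  # |log variance| bound for the optimizer; exp(-23) ~ 1e-10


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the incumbent log-likelihood trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class RandomSpec:
    """One random term.

    ``factor`` names the grouping column (e.g. ``genotype``). If ``by`` is
    given the term is factor-by-``by`` (e.g. genotype-by-evaluation-time) and
    ``structure`` describes the covariance among ``by`` levels: ``idv``
    (sigma^2 I), ``diag``, ``cs`` or ``us``. Plain factors are always IDV.
    """

    factor: str
    structure: str = "idv"
    by: str | None = None

    def __post_init__(self) -> None:
        if self.structure not in ("idv", "diag", "cs", "us"):
            raise ValueError(f"unknown covariance structure {self.structure!r}")
        if self.by is None and self.structure != "idv":
            raise ValueError("structured covariances require an interaction ('by') column")

    @property
    def name(self) -> str:
        return self.factor if self.by is None else f"{self.factor}:{self.by}"


@dataclass(frozen=True)
class ResidualSpec:
    """Residual covariance: homogeneous (by=None) or diagonal by a column."""

    by: str | None = None

    @property
    def name(self) -> str:
        return "iid" if self.by is None else f"diag({self.by})"


@dataclass(frozen=True)
class ModelSpec:
    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[RandomSpec, ...] = (RandomSpec("genotype"),)
    residual: ResidualSpec = ResidualSpec()

    def describe(self) -> str:
        rand = " + ".join(f"{r.name}[{r.structure}]" for r in self.random)
        fixed = " + ".join(("1",) + self.fixed)
        return f"{self.response} ~ {fixed} + ({rand}); resid {self.residual.name}"


# ---------------------------------------------------------------------------
# design construction


def _one_hot(idx: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((idx.size, n_levels))
    Z[np.arange(idx.size), idx] = 1.0
    return Z


def _factorize(col: pd.Series) -> tuple[np.ndarray, list]:
    levels = sorted(col.unique())
    mapping = {lvl: k for k, lvl in enumerate(levels)}
    return col.map(mapping).to_numpy(), levels


@dataclass
class _Term:
    spec: RandomSpec
    Z: np.ndarray  # n × q dense incidence
    n_outer: int  # levels of `factor`
    t: int  # levels of `by` (1 for plain factors)
    outer_levels: list
    inner_levels: list

    @property
    def q(self) -> int:
        return self.n_outer * self.t

    @property
    def n_params(self) -> int:
        return {"idv": 1, "diag": self.t, "cs": 2, "us": self.t * (self.t + 1) // 2}[
            self.spec.structure
        ]


def _build_fixed(data: pd.DataFrame, fixed: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    n = len(data)
    cols = [np.ones(n)]
    names = ["(intercept)"]
    for f in fixed:
        idx, levels = _factorize(data[f])
        for k in range(1, len(levels)):  # drop first level
            cols.append((idx == k).astype(float))
            names.append(f"{f}[{levels[k]}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = [names[j] for j in piv[rank:]]
        raise ValueError(f"fixed design is rank deficient; aliased terms: {aliased}")
    return X, names


def _build_term(data: pd.DataFrame, spec: RandomSpec) -> _Term:
    fidx, flevels = _factorize(data[spec.factor])
    if len(flevels) < 2:
        raise ValueError(f"random factor {spec.factor!r} needs >= 2 levels")
    if spec.by is None:
        Z = _one_hot(fidx, len(flevels))
        return _Term(spec, Z, len(flevels), 1, flevels, [None])
    bidx, blevels = _factorize(data[spec.by])
    if len(blevels) < 2:
        raise ValueError(f"interaction column {spec.by!r} needs >= 2 levels")
    t, nf = len(blevels), len(flevels)
    # inner-major ordering: column = by_level * n_factor + factor_level,
    # so the term covariance is kron(G0, I_nf)
    Z = _one_hot(bidx * nf + fidx, t * nf)
    return _Term(spec, Z, nf, t, flevels, blevels)


# ---------------------------------------------------------------------------
# covariance parameterizations


def _cs_rho_bounds(t: int) -> tuple[float, float]:
    return -1.0 / (t - 1) + 1e-6, 1.0 - 1e-6


def _g0_from_theta(structure: str, t: int, theta: np.ndarray) -> np.ndarray:
    if structure == "idv":
        return np.exp(theta[0]) * np.eye(t)
    if structure == "diag":
        return np.diag(np.exp(theta))
    if structure == "cs":
        v = np.exp(theta[0])
        lo, hi = _cs_rho_bounds(t)
        rho = lo + (hi - lo) / (1.0 + np.exp(-theta[1]))
        return v * ((1 - rho) * np.eye(t) + rho * np.ones((t, t)))
    if structure == "us":
        L = np.zeros((t, t))
        k = 0
        for i in range(t):
            for j in range(i + 1):
                L[i, j] = np.exp(theta[k]) if i == j else theta[k]
                k += 1
        return L @ L.T
    raise ValueError(structure)


def _theta_start(structure: str, t: int, v0: float) -> np.ndarray:
    if structure == "idv":
        return np.array([np.log(v0)])
    if structure == "diag":
        return np.full(t, np.log(v0))
    if structure == "cs":
        lo, hi = _cs_rho_bounds(t)
        u0 = np.log((0.0 - lo) / (hi - 0.0))  # rho = 0
        return np.array([np.log(v0), u0])
    if structure == "us":
        theta = []
        for i in range(t):
            for j in range(i + 1):
                theta.append(0.5 * np.log(v0) if i == j else 0.0)
        return np.asarray(theta)
    raise ValueError(structure)


# ---------------------------------------------------------------------------
# fit result


@dataclass
class ModelFit:
    spec: ModelSpec
    varcomps: dict[str, float | np.ndarray]
    residual_var: float | dict
    beta: pd.Series
    blups: dict[str, pd.Series]
    pev: dict[str, np.ndarray]
    loglik: float
    n_params: int
    n_obs: int
    rank_X: int
    converged: bool
    n_iter: int
    ll_trace: list[float] = field(default_factory=list, repr=False)

    @property
    def aic(self) -> float:
        return information_criteria(self)[0]

    @property
    def bic(self) -> float:
        return information_criteria(self)[1]

    @property
    def bicc(self) -> float:
        return information_criteria(self)[2]

    # convenience accessors for the genotype term
    def _genotype_name(self) -> str:
        for r in self.spec.random:
            if r.by is None and r.factor == "genotype":
                return r.name
        raise KeyError("model has no plain genotype term")

    @property
    def sigma2_g(self) -> float:
        g = self.varcomps[self._genotype_name()]
        return float(g)

    @property
    def genotype_blups(self) -> pd.Series:
        return self.blups[self._genotype_name()]

    @property
    def pev_matrix(self) -> np.ndarray:
        return self.pev[self._genotype_name()]


# ---------------------------------------------------------------------------
# REML core


class _REMLProblem:
    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        y = data["value"].to_numpy(dtype=float)
        self.n = y.size
        self.X, self.fixed_names = _build_fixed(data, spec.fixed)
        self.p = self.X.shape[1]
        self.terms = [_build_term(data, r) for r in spec.random]
        self.Z = (
            np.hstack([t.Z for t in self.terms])
            if self.terms
            else np.zeros((self.n, 0))
        )
        self.q = self.Z.shape[1]
        self.spec = spec

        # internal scaling for optimizer conditioning
        s = float(np.std(y))
        self.scale = s if s > 0 else 1.0
        self.y = y
        ys = y / self.scale

        if spec.residual.by is None:
            ridx = np.zeros(self.n, dtype=int)
            self.resid_levels: list = [None]
        else:
            ridx, self.resid_levels = _factorize(data[spec.residual.by])
            if len(self.resid_levels) < 2:
                raise ValueError(
                    f"residual grouping {spec.residual.by!r} needs >= 2 levels"
                )
        self.n_resid = len(self.resid_levels)
        self.ridx = ridx

        B = np.column_stack([self.X, self.Z, ys])
        d = B.shape[1]
        self.grams = np.zeros((self.n_resid, d, d))
        self.group_n = np.zeros(self.n_resid)
        for k in range(self.n_resid):
            Bk = B[ridx == k]
            self.grams[k] = Bk.T @ Bk
            self.group_n[k] = Bk.shape[0]

        self.term_sizes = [t.n_params for t in self.terms]
        self.n_theta = sum(self.term_sizes) + self.n_resid

    def split_theta(self, theta: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        parts = []
        off = 0
        for sz in self.term_sizes:
            parts.append(theta[off : off + sz])
            off += sz
        return parts, theta[off:]

    def _g_blocks(self, term_thetas: list[np.ndarray]):
        """Per-term (G0, G0inv, logdet of full block)."""
        out = []
        for term, th in zip(self.terms, term_thetas):
            G0 = _g0_from_theta(term.spec.structure, term.t, th)
            sign, ld0 = np.linalg.slogdet(G0)
            if sign <= 0:
                return None
            G0inv = np.linalg.inv(G0)
            out.append((G0, G0inv, term.n_outer * ld0))
        return out

    def _ginv_full(self, blocks) -> np.ndarray:
        Ginv = np.zeros((self.q, self.q))
        off = 0
        for term, (_, G0inv, _) in zip(self.terms, blocks):
            qt = term.q
            if term.t == 1:
                Ginv[off : off + qt, off : off + qt] = G0inv[0, 0] * np.eye(qt)
            else:
                Ginv[off : off + qt, off : off + qt] = np.kron(G0inv, np.eye(term.n_outer))
            off += qt
        return Ginv

    def _penalty(self, theta: np.ndarray) -> float:
        # smooth ascent away from numerically infeasible regions so line
        # searches that overshoot get a slope back toward feasibility
        return 1e8 * (1.0 + float(np.sum(theta**2)))

    @staticmethod
    def _chol_with_jitter(A: np.ndarray):
        """Cholesky with escalating diagonal jitter; None if hopeless.

        Keeps the restricted likelihood finite (and sloped) in nearly
        singular corners of the parameter space that line searches cross.
        """
        try:
            return linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError:
            pass
        scale = max(float(np.trace(A)) / max(A.shape[0], 1), 1e-300)
        for eps in (1e-10, 1e-8, 1e-6):
            try:
                return linalg.cho_factor(
                    A + eps * scale * np.eye(A.shape[0]), lower=True
                )
            except linalg.LinAlgError:
                continue
        return None

    def negloglik(self, theta: np.ndarray) -> float:
        term_thetas, resid_theta = self.split_theta(theta)
        blocks = self._g_blocks(term_thetas)
        if blocks is None:
            return self._penalty(theta)
        sig2 = np.exp(resid_theta)
        w = 1.0 / sig2
        S = np.tensordot(w, self.grams, axes=(0, 0))
        p, q = self.p, self.q
        XtX = S[:p, :p]
        XtZ = S[:p, p : p + q]
        Xty = S[:p, -1]
        ZtZ = S[p : p + q, p : p + q]
        Zty = S[p : p + q, -1]
        yty = S[-1, -1]

        logdetR = float(np.dot(self.group_n, np.log(sig2)))
        logdetG = sum(b[2] for b in blocks)
        if q > 0:
            Ginv = self._ginv_full(blocks)
            cM = self._chol_with_jitter(ZtZ + Ginv)
            if cM is None:
                return self._penalty(theta)
            logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
            MiZtX = linalg.cho_solve(cM, XtZ.T)  # q × p
            MiZty = linalg.cho_solve(cM, Zty)
            XtViX = XtX - XtZ @ MiZtX
            XtViy = Xty - XtZ @ MiZty
            ytViy = yty - Zty @ MiZty
        else:
            logdetM = 0.0
            XtViX, XtViy, ytViy = XtX, Xty, yty
        cF = self._chol_with_jitter(XtViX)
        if cF is None:
            return self._penalty(theta)
        logdetF = 2.0 * np.sum(np.log(np.diag(cF[0])))
        beta = linalg.cho_solve(cF, XtViy)
        yPy = ytViy - XtViy @ beta

        ll = -0.5 * (logdetR + logdetG + logdetM + logdetF + yPy + (self.n - p) * _LOG2PI)
        if not np.isfinite(ll):
            return self._penalty(theta)
        return -ll

    def loglik_original_scale(self, negll_scaled: float) -> float:
        return -negll_scaled - (self.n - self.p) * np.log(self.scale)

    def start(self) -> np.ndarray:
        n_blocks = len(self.terms) + 1
        v0 = 1.0 / n_blocks  # scaled y has variance ~1
        parts = [
            _theta_start(t.spec.structure, t.t, v0) for t in self.terms
        ]
        parts.append(np.full(self.n_resid, np.log(v0)))
        return np.concatenate(parts)

    def solve_mme(self, theta: np.ndarray):
        """Mixed-model equations on the ORIGINAL scale at parameters theta."""
        term_thetas, resid_theta = self.split_theta(theta)
        blocks = self._g_blocks(term_thetas)
        sig2 = np.exp(resid_theta) * self.scale**2
        w = 1.0 / sig2
        wrow = w[self.ridx]
        X, Z, y = self.X, self.Z, self.y
        Xw = X * wrow[:, None]
        Zw = Z * wrow[:, None]
        Ginv = self._ginv_full(blocks) / self.scale**2
        p, q = self.p, self.q
        C = np.zeros((p + q, p + q))
        C[:p, :p] = X.T @ Xw
        C[:p, p:] = Xw.T @ Z
        C[p:, :p] = C[:p, p:].T
        C[p:, p:] = Z.T @ Zw + Ginv
        rhs = np.concatenate([Xw.T @ y, Zw.T @ y])
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        return sol[:p], sol[p:], Cinv, sig2


def fit_reml(
    data: pd.DataFrame,
    spec: ModelSpec,
    max_iter: int = 500,
    polish: bool = True,
) -> ModelFit:
    """Fit one trait's mixed model by REML and return components, BLUPs, PEV.

    ``data`` is the long phenotype table; rows are filtered to
    ``trait == spec.response`` when a ``trait`` column is present, and rows
    with missing values are dropped (the engine handles unbalanced data).
    """
    df = data
    if "trait" in df.columns:
        df = df[df["trait"] == spec.response]
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValueError(f"no observations for trait {spec.response!r}")
    df = df.sort_index()
    if spec.random:
        gcount = df.groupby(df[spec.random[0].factor]).size()
        if len(gcount) < 2 or gcount.max() < 2:
            raise ValueError("need >= 2 genotypes with >= 2 observations")

    prob = _REMLProblem(df.reset_index(drop=True), spec)
    x0 = prob.start()
    trace: list[float] = []
    best = {"f": np.inf, "x": x0}

    def wrapped(theta: np.ndarray) -> float:
        f = prob.negloglik(theta)
        if f < best["f"]:
            best["f"] = f
            best["x"] = theta.copy()
        trace.append(-min(f, best["f"]))
        return f

    bounds = [(-_BOUND, _BOUND)] * prob.n_theta
    res = optimize.minimize(
        wrapped,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    n_iter = res.nit
    # L-BFGS line searches can stall against the infeasibility penalty, so a
    # simplex refinement from the incumbent best always follows; with
    # polish=True it runs to tight tolerances, otherwise on a short budget,
    # restarted once if it was still improving when the budget ran out.
    xatol, fatol = (1e-10, 1e-12) if polish else (1e-7, 1e-9)
    budget = (200 if polish else 80) * prob.n_theta
    converged = False
    f_last_round = np.inf
    for _ in range(3):
        f_before = best["f"]
        res2 = optimize.minimize(
            wrapped,
            best["x"],
            method="Nelder-Mead",
            options={"maxiter": budget, "xatol": xatol, "fatol": fatol},
        )
        n_iter += res2.nit
        f_last_round = abs(f_before - best["f"])
        if res2.success:
            converged = True
            break
        if f_last_round <= 1e-8 * max(1.0, abs(best["f"])):
            converged = True  # no further progress: flat optimum
            break
    if not converged:
        # budget exhausted: accept when the last full restart moved the
        # objective by a negligible amount relative to its magnitude
        converged = f_last_round <= 1e-5 * max(1.0, abs(best["f"]))
    if not np.isfinite(best["f"]) or best["f"] >= 1e9:
        raise ConvergenceError(
            f"REML failed to find a finite optimum for {spec.response!r}", trace
        )
    if not converged:
        raise ConvergenceError(
            f"REML did not converge within {max_iter} iterations for {spec.response!r}",
            trace,
        )

    theta = best["x"]
    loglik = prob.loglik_original_scale(best["f"])
    term_thetas, resid_theta = prob.split_theta(theta)

    varcomps: dict[str, float | np.ndarray] = {}
    for term, th in zip(prob.terms, term_thetas):
        G0 = _g0_from_theta(term.spec.structure, term.t, th) * prob.scale**2
        varcomps[term.spec.name] = float(G0[0, 0]) if term.t == 1 else G0
    sig2 = np.exp(resid_theta) * prob.scale**2
    residual_var: float | dict
    if spec.residual.by is None:
        residual_var = float(sig2[0])
    else:
        residual_var = {str(lvl): float(v) for lvl, v in zip(prob.resid_levels, sig2)}

    beta_vec, u, Cinv, _ = prob.solve_mme(theta)
    beta = pd.Series(beta_vec, index=prob.fixed_names)
    blups: dict[str, pd.Series] = {}
    pev: dict[str, np.ndarray] = {}
    off = 0
    for term in prob.terms:
        qt = term.q
        sl = slice(prob.p + off, prob.p + off + qt)
        block = Cinv[sl, sl]
        if term.t == 1:
            idx = pd.Index(term.outer_levels, name=term.spec.factor)
            blups[term.spec.name] = pd.Series(u[off : off + qt], index=idx)
            pev[term.spec.name] = block
        else:
            midx = pd.MultiIndex.from_product(
                [term.inner_levels, term.outer_levels],
                names=[term.spec.by, term.spec.factor],
            )
            blups[term.spec.name] = pd.Series(u[off : off + qt], index=midx)
            pev[term.spec.name] = block
        off += qt

    # monotone incumbent-best log-likelihood trace
    mono = list(np.maximum.accumulate(trace))
    return ModelFit(
        spec=spec,
        varcomps=varcomps,
        residual_var=residual_var,
        beta=beta,
        blups=blups,
        pev=pev,
        loglik=float(loglik),
        n_params=prob.n_theta,
        n_obs=prob.n,
        rank_X=prob.p,
        converged=converged,
        n_iter=int(n_iter),
        ll_trace=mono,
    )


# ---------------------------------------------------------------------------
# genetic parameters and model comparison


def information_criteria(
    fit: ModelFit | None = None,
    loglik: float | None = None,
    n_params: int | None = None,
    n_obs: int | None = None,
    rank_x: int | None = None,
) -> tuple[float, float, float]:
    """AIC, BIC and BICc from a REML fit.

    AIC = -2l + 2p; BIC = -2l + p log(n); BICc = -2l + p log(n - rank X),
    with p the number of (co)variance parameters and the BICc sample size the
    REML effective size (observations minus fixed-effect rank).
    """
    if fit is not None:
        loglik, n_params, n_obs, rank_x = fit.loglik, fit.n_params, fit.n_obs, fit.rank_X
    assert loglik is not None and n_params is not None and n_obs is not None
    m2l = -2.0 * loglik
    aic = m2l + 2.0 * n_params
    bic = m2l + n_params * np.log(n_obs)
    nstar = n_obs - (rank_x or 0)
    bicc = m2l + n_params * np.log(nstar) if nstar > 0 else np.nan
    return float(aic), float(bic), float(bicc)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt(full: ModelFit, reduced: ModelFit, boundary: bool = False) -> LRTResult:
    """Likelihood-ratio test of nested variance structures.

    Plain chi-square with df = parameter-count difference; ``boundary=True``
    switches to the 0.5 chi2_0 + 0.5 chi2_1 mixture for a single variance
    component tested on its boundary (conservative otherwise).
    """
    if full.spec.response != reduced.spec.response:
        raise ValueError("LRT requires the same response in both models")
    if full.spec.fixed != reduced.spec.fixed:
        raise ValueError("LRT requires identical fixed effects (REML likelihoods)")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("models are not nested: 'full' has fewer parameters")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-2:
        warnings.warn(
            f"negative LRT statistic {stat:.3g}; likely convergence noise", stacklevel=2
        )
    stat = max(stat, 0.0)
    df_eff = max(df, 1)
    if boundary and df_eff == 1:
        p = 0.5 * stats.chi2.sf(stat, 1) + (0.5 if stat == 0.0 else 0.0)
    else:
        p = stats.chi2.sf(stat, df_eff)
    return LRTResult(statistic=float(stat), df=df_eff, p_value=float(p))


def cullis_heritability(fit: ModelFit, method: str = "pairs") -> float:
    """Generalized broad-sense heritability H² = 1 - mean Δ_BLUP / (2 σ²_g).

    ``method='pairs'`` averages var(ĝ_i - ĝ_j) = PEV_ii + PEV_jj - 2 PEV_ij
    over all genotype pairs i<j; ``method='mean-pev'`` uses 2·mean(PEV_ii)
    (the approximation some software applies).
    """
    sg = fit.sigma2_g
    P = fit.pev_matrix
    if sg <= 1e-12:
        warnings.warn("sigma2_g at the zero boundary; H² reported as 0", stacklevel=2)
        return 0.0
    n = P.shape[0]
    if method == "pairs":
        tr = np.trace(P)
        total = P.sum()
        delta_sum = (n - 1) * tr - (total - tr)
        delta_bar = delta_sum / (n * (n - 1) / 2.0)
    elif method == "mean-pev":
        delta_bar = 2.0 * np.mean(np.diag(P))
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(1.0 - delta_bar / (2.0 * sg))


def prediction_accuracy(fit: ModelFit, tol: float = 1e-8) -> tuple[pd.Series, float]:
    """Per-genotype accuracy r_i = sqrt(1 - PEV_ii / σ²_g) and its mean."""
    sg = fit.sigma2_g
    if sg <= 1e-12:
        raise ValueError("prediction accuracy undefined with sigma2_g at 0")
    pev_ii = np.diag(fit.pev_matrix)
    ratio = pev_ii / sg
    r = np.full(ratio.shape, np.nan)
    ok = ratio <= 1.0 + tol
    r[ok] = np.sqrt(np.clip(1.0 - ratio[ok], 0.0, 1.0))
    if (~ok).any():
        warnings.warn(
            f"{(~ok).sum()} genotypes with PEV exceeding sigma2_g beyond tolerance",
            stacklevel=2,
        )
    series = pd.Series(r, index=fit.genotype_blups.index, name="accuracy")
    return series, float(np.nanmean(r))


def select_structure(
    data: pd.DataFrame,
    candidates: list[ModelSpec],
    criterion: str = "aic",
) -> tuple[pd.DataFrame, ModelSpec, dict[str, ModelFit]]:
    """Fit candidate variance structures and rank them by an information criterion.

    Non-converged candidates are flagged and excluded from the ranking; ties
    on the criterion go to the candidate with fewer parameters.
    """
    if criterion not in ("aic", "bic", "bicc"):
        raise ValueError("criterion must be one of aic, bic, bicc")
    if not candidates:
        raise ValueError("no candidate specifications given")
    rows = []
    fits: dict[str, ModelFit] = {}
    for spec in candidates:
        name = spec.describe()
        try:
            fit = fit_reml(data, spec)
            fits[name] = fit
            aic, bic, bicc = information_criteria(fit)
            rows.append(
                {
                    "model": name,
                    "n_params": fit.n_params,
                    "loglik": fit.loglik,
                    "aic": aic,
                    "bic": bic,
                    "bicc": bicc,
                    "converged": True,
                }
            )
        except (ConvergenceError, ValueError) as exc:
            rows.append(
                {
                    "model": name,
                    "n_params": np.nan,
                    "loglik": np.nan,
                    "aic": np.nan,
                    "bic": np.nan,
                    "bicc": np.nan,
                    "converged": False,
                }
            )
            warnings.warn(f"candidate {name} failed: {exc}", stacklevel=2)
    table = pd.DataFrame(rows)
    ok = table[table["converged"]]
    if ok.empty:
        raise RuntimeError("all candidate structures failed to converge")
    ok = ok.sort_values([criterion, "n_params"], kind="mergesort")
    best_name = ok.iloc[0]["model"]
    best_spec = next(c for c in candidates if c.describe() == best_name)
    table = table.sort_values([criterion, "n_params"], na_position="last", kind="mergesort")
    return table.reset_index(drop=True), best_spec, fits


# ---------------------------------------------------------------------------
# bivariate REML (genetic correlation)


@dataclass
class BivariateFit:
    traits: tuple[str, str]
    G0: np.ndarray  # 2×2 genetic covariance
    R0: np.ndarray  # 2×2 residual covariance
    loglik: float
    converged: bool
    n_genotypes: int
    n_units: int

    @property
    def genetic_correlation(self) -> float:
        d = np.diag(self.G0)
        if (d <= 1e-10 * max(np.trace(self.R0), 1e-300)).any():
            warnings.warn(
                "a genetic variance is at the zero boundary; r_g undefined", stacklevel=2
            )
            return float("nan")
        return float(self.G0[0, 1] / np.sqrt(d[0] * d[1]))


def _chol2_from_theta(theta: np.ndarray) -> np.ndarray:
    L = np.array([[np.exp(theta[0]), 0.0], [theta[1], np.exp(theta[2])]])
    return L @ L.T


def fit_bivariate_reml(
    data: pd.DataFrame,
    trait1: str,
    trait2: str,
    unit_cols: tuple[str, ...] = ("genotype", "replicate"),
    max_iter: int = 500,
) -> BivariateFit:
    """Bivariate REML with unstructured 2×2 genetic and residual covariances.

    Both traits must be observed on shared experimental units (identified by
    ``unit_cols``); incomplete units are dropped. The stacked model has a
    per-trait intercept, a bivariate genotype effect with covariance
    G0 ⊗ I, and residual covariance R0 ⊗ I across the paired units.
    """
    df = data[data["trait"].isin([trait1, trait2])]
    wide = df.pivot_table(index=list(unit_cols), columns="trait", values="value")
    if trait1 not in wide.columns or trait2 not in wide.columns:
        raise ValueError("both traits must be present in the data")
    wide = wide[[trait1, trait2]].dropna()
    if len(wide) < 4:
        raise ValueError("too few complete units for a bivariate fit")
    y1 = wide[trait1].to_numpy(float)
    y2 = wide[trait2].to_numpy(float)
    geno = wide.index.get_level_values("genotype")
    gidx, glevels = _factorize(pd.Series(geno))
    q0 = len(glevels)
    n0 = len(wide)
    Z0 = _one_hot(gidx, q0)
    X0 = np.ones((n0, 1))
    p0 = 1

    A = np.hstack([X0, Z0])
    AtA = A.T @ A
    Aty = np.column_stack([A.T @ y1, A.T @ y2])  # (p0+q0) × 2
    yy = np.array([[y1 @ y1, y1 @ y2], [y1 @ y2, y2 @ y2]])
    X0tX0 = AtA[:p0, :p0]
    X0tZ0 = AtA[:p0, p0:]
    Z0tZ0 = AtA[p0:, p0:]
    p = 2 * p0
    q = 2 * q0
    I_q0 = np.eye(q0)

    def negll(theta: np.ndarray) -> float:
        G0 = _chol2_from_theta(theta[:3])
        R0 = _chol2_from_theta(theta[3:])
        sG, ldG0 = np.linalg.slogdet(G0)
        sR, ldR0 = np.linalg.slogdet(R0)
        if sG <= 0 or sR <= 0:
            return 1e10
        S = np.linalg.inv(R0)
        G0inv = np.linalg.inv(G0)

        XtRiX = np.kron(S, X0tX0)
        XtRiZ = np.kron(S, X0tZ0)
        ZtRiZ = np.kron(S, Z0tZ0)
        Ginv = np.kron(G0inv, I_q0)
        Xty_blocks = Aty[:p0] @ S  # p0 × 2; column i = X0' * sum_j S_ij y_j
        Zty_blocks = Aty[p0:] @ S
        XtRiy = Xty_blocks.T.reshape(-1)
        ZtRiy = Zty_blocks.T.reshape(-1)
        ytRiy = float(np.sum(S * yy))

        try:
            cM = linalg.cho_factor(ZtRiZ + Ginv, lower=True)
        except linalg.LinAlgError:
            return 1e10
        logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
        MiZtX = linalg.cho_solve(cM, XtRiZ.T)
        MiZty = linalg.cho_solve(cM, ZtRiy)
        XtViX = XtRiX - XtRiZ @ MiZtX
        XtViy = XtRiy - XtRiZ @ MiZty
        ytViy = ytRiy - ZtRiy @ MiZty
        try:
            cF = linalg.cho_factor(XtViX, lower=True)
        except linalg.LinAlgError:
            return 1e10
        logdetF = 2.0 * np.sum(np.log(np.diag(cF[0])))
        beta = linalg.cho_solve(cF, XtViy)
        yPy = ytViy - XtViy @ beta
        n_all = 2 * n0
        ll = -0.5 * (
            n0 * ldR0
            + q0 * ldG0
            + logdetM
            + logdetF
            + yPy
            + (n_all - p) * _LOG2PI
        )
        return -ll

    v1, v2 = np.var(y1, ddof=1), np.var(y2, ddof=1)
    x0 = np.array(
        [
            0.5 * np.log(0.5 * v1),
            0.0,
            0.5 * np.log(0.5 * v2),
            0.5 * np.log(0.5 * v1),
            0.0,
            0.5 * np.log(0.5 * v2),
        ]
    )
    best = {"f": np.inf, "x": x0}

    def wrapped(th):
        f = negll(th)
        if f < best["f"]:
            best["f"], best["x"] = f, th.copy()
        return f

    res = optimize.minimize(
        wrapped, x0, method="L-BFGS-B", options={"maxiter": max_iter, "ftol": 1e-13}
    )
    res2 = optimize.minimize(
        wrapped,
        best["x"],
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-9, "fatol": 1e-11},
    )
    converged = bool(res.success or res2.success)
    if not converged or best["f"] >= 1e9:
        raise ConvergenceError("bivariate REML did not converge", [])
    theta = best["x"]
    return BivariateFit(
        traits=(trait1, trait2),
        G0=_chol2_from_theta(theta[:3]),
        R0=_chol2_from_theta(theta[3:]),
        loglik=float(-best["f"]),
        converged=converged,
        n_genotypes=q0,
        n_units=n0,
    )
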