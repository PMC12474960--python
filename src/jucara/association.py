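"""Trait associations: correlation matrices, VIF screening, path analysis.

Phenotypic correlations are Pearson coefficients among genotype-level trait
values; genetic correlations come from a bivariate REML fit (or, as a fast
fallback, from correlating univariate BLUPs). Before decomposing
correlations with the response into direct and indirect effects, collinear
explanatory traits are removed iteratively by the variance inflation factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from jucara import lmm

log = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # symmetric, unit diagonal
    p: pd.DataFrame  # two-sided p-values (NaN on the diagonal)
    level: str  # "phenotypic" or "genetic"

    @property
    def labels(self) -> list[str]:
        return list(self.r.columns)


def _corr_pvalue(r: float, n: int) -> float:
    if n <= 2 or not np.isfinite(r):
        return float("nan")
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def phenotypic_correlation(table: pd.DataFrame, min_pairs: int = 3) -> CorrelationMatrix:
    """Pearson correlations among trait columns on pairwise-complete rows.

    ``table`` is genotype-level (one row per genotype, one column per trait).
    Zero-variance traits get NaN coefficients and are logged.
    """
    traits = list(table.columns)
    k = len(traits)
    R = np.full((k, k), np.nan)
    P = np.full((k, k), np.nan)
    for i in range(k):
        R[i, i] = 1.0
        xi = table[traits[i]]
        for j in range(i + 1, k):
            pair = pd.concat([xi, table[traits[j]]], axis=1).dropna()
            if len(pair) < min_pairs:
                continue
            a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(a) == 0 or np.std(b) == 0:
                log.warning(
                    "zero-variance trait in pair (%s, %s); correlation undefined",
                    traits[i],
                    traits[j],
                )
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = _corr_pvalue(r, len(pair))
    idx = pd.Index(traits)
    return CorrelationMatrix(
        r=pd.DataFrame(R, index=idx, columns=idx),
        p=pd.DataFrame(P, index=idx, columns=idx),
        level="phenotypic",
    )


def genetic_correlation(
    data: pd.DataFrame,
    trait1: str,
    trait2: str,
    method: str = "reml",
    unit_cols: tuple[str, ...] = ("genotype", "replicate"),
) -> tuple[float, float]:
    """Genetic correlation between two traits and an approximate p-value.

    ``method='reml'`` fits the unstructured bivariate mixed model and returns
    r_g = cov_g / sqrt(var_g1 var_g2). ``method='blup'`` correlates
    univariate BLUPs (fast, slightly deflated). The p-value is a t-test with
    effective n = number of genotypes — approximate, since no exact sampling
    distribution is available for r_g.
    """
    if method == "reml":
        fit = lmm.fit_bivariate_reml(data, trait1, trait2, unit_cols=unit_cols)
        r = fit.genetic_correlation
        n = fit.n_genotypes
    elif method == "blup":
        f1 = lmm.fit_reml(data, lmm.ModelSpec(response=trait1))
        f2 = lmm.fit_reml(data, lmm.ModelSpec(response=trait2))
        b = pd.concat([f1.genotype_blups, f2.genotype_blups], axis=1).dropna()
        r = float(np.corrcoef(b.iloc[:, 0], b.iloc[:, 1])[0, 1])
        n = len(b)
    else:
        raise ValueError(f"unknown method {method!r}")
    return r, _corr_pvalue(r, n)


def genetic_correlation_matrix(
    data: pd.DataFrame,
    traits: list[str],
    method: str = "blup",
    unit_cols: tuple[str, ...] = ("genotype", "replicate"),
) -> CorrelationMatrix:
    """All-pairs genetic correlations (default: fast BLUP-correlation route)."""
    k = len(traits)
    R = np.eye(k)
    P = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                r, p = genetic_correlation(
                    data, traits[i], traits[j], method=method, unit_cols=unit_cols
                )
            except (ValueError, lmm.ConvergenceError) as exc:
                log.warning("genetic correlation (%s, %s) failed: %s", traits[i], traits[j], exc)
                r, p = np.nan, np.nan
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    idx = pd.Index(traits)
    return CorrelationMatrix(
        r=pd.DataFrame(R, index=idx, columns=idx),
        p=pd.DataFrame(P, index=idx, columns=idx),
        level="genetic",
    )


def vif_filter(
    C: pd.DataFrame, threshold: float = 5.0
) -> tuple[list[str], pd.DataFrame]:
    """Iteratively drop the highest-VIF trait until all VIF <= threshold.

    VIF_i is the i-th diagonal of the inverse correlation matrix among the
    explanatory traits (equivalently 1/(1-R²_i) of the auxiliary regression
    of trait i on the rest). Returns the retained trait list and a table of
    all traits with their final (or at-removal) VIF.
    """
    traits = list(C.columns)
    retained = traits.copy()
    records: dict[str, tuple[float, bool]] = {}
    while True:
        sub = C.loc[retained, retained].to_numpy()
        if np.linalg.cond(sub) > 1e12:
            # try removing each trait once; if no single removal fixes it, fail
            fixed = False
            for cand in retained:
                rest = [t for t in retained if t != cand]
                if len(rest) >= 1 and np.linalg.cond(C.loc[rest, rest].to_numpy()) <= 1e12:
                    records[cand] = (float("inf"), True)
                    retained = rest
                    fixed = True
                    break
            if fixed:
                continue
            raise ValueError(
                f"correlation matrix singular; collinear block among {retained}"
            )
        vif = np.diag(np.linalg.inv(sub))
        worst = int(np.argmax(vif))
        if vif[worst] > threshold and len(retained) > 1:
            name = retained[worst]
            records[name] = (float(vif[worst]), True)
            retained.pop(worst)
            continue
        for name, v in zip(retained, vif):
            records[name] = (float(v), False)
        break
    table = pd.DataFrame(
        [(t, records[t][0], records[t][1]) for t in traits],
        columns=["trait", "vif", "excluded"],
    )
    return retained, table


@dataclass
class PathResult:
    response: str
    traits: list[str]
    direct: pd.Series  # path coefficients
    indirect: pd.DataFrame  # indirect[i, j] = effect of i via j (NaN diagonal)
    r_response: pd.Series
    r_squared: float
    residual_effect: float  # EVR = sqrt(1 - R²)
    excluded: pd.DataFrame = field(default_factory=pd.DataFrame)


def path_analysis(
    C: pd.DataFrame, r_y: pd.Series, response: str = "response"
) -> PathResult:
    """Decompose correlations with the response into direct/indirect effects.

    Solves C p = r_y for the direct effects p over the retained explanatory
    traits; the indirect effect of trait i via trait j is C_ij p_j. The
    coefficient of determination is R² = p·r_y and the residual variable
    effect is sqrt(1 - R²). ``C`` must be positive definite (run vif_filter
    first).
    """
    traits = list(C.columns)
    r_y = r_y.loc[traits]
    A = C.to_numpy()
    w = np.linalg.eigvalsh(A)
    if w.min() <= 1e-10:
        raise ValueError(
            "explanatory correlation matrix is not positive definite; "
            "apply vif_filter before path analysis"
        )
    p = np.linalg.solve(A, r_y.to_numpy())
    indirect = A * p[None, :]
    np.fill_diagonal(indirect, np.nan)
    r2 = float(p @ r_y.to_numpy())
    if r2 > 1.0 + 1e-10:
        warnings.warn(f"R² = {r2:.4f} > 1; inconsistent correlation inputs", stacklevel=2)
    evr = float(np.sqrt(max(1.0 - r2, 0.0)))
    idx = pd.Index(traits)
    return PathResult(
        response=response,
        traits=traits,
        direct=pd.Series(p, index=idx, name="direct"),
        indirect=pd.DataFrame(indirect, index=idx, columns=idx),
        r_response=r_y,
        r_squared=r2,
        residual_effect=evr,
    )
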