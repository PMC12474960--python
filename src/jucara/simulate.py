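"""Synthetic phenotype and SSR genotype generators with known ground truth.

Each generator draws from the same statistical model the analysis modules
assume, so parameter-recovery tests have an exact truth to compare against:

* biometric traits  — intercept + fixed replicate effects + IID genotype
  effects + IID residual;
* emergence traits  — adds an IID elevation-class effect and residual
  variances heterogeneous across field-sampling groups, plus per-box
  emergence count series for the derived-trait module;
* growth traits     — adds a genotype-by-evaluation-time effect with an
  arbitrary t×t covariance among times and time-specific residual variances;
* SSR genotypes     — diploid draws per locus under a given allele-frequency
  vector and inbreeding coefficient F (negative F = heterozygote excess).

Randomness contract: one root seed; each generator uses its own
deterministically derived substream, so adding or re-running one generator
never perturbs another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENOTYPE_COLUMNS = [
    "genotype",
    "group",
    "replicate",
    "elevation",
    "eval_time",
    "trait",
    "value",
]

# Substream keys: stable per generator.
_STREAMS = {
    "biometric": 1,
    "emergence": 2,
    "growth": 3,
    "ssr": 4,
    "missing": 5,
    "clustered": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


def _check_psd(m: np.ndarray, name: str) -> None:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    w = np.linalg.eigvalsh(m)
    if w.min() < -1e-10:
        raise ValueError(f"{name} must be positive semidefinite (min eigenvalue {w.min():.3g})")


def _check_var(v: float, name: str) -> float:
    v = float(v)
    if not np.isfinite(v) or v < 0:
        raise ValueError(f"{name} must be a finite nonnegative variance, got {v!r}")
    return v


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the field study the generators emulate: 72 founder
    genotypes; 10 replicates for biometric/growth traits and 4 boxes of 25
    seeds for emergence; 5 evaluation times for growth; 59 genotyped
    individuals at 8 SSR loci with the observed allele counts
    (8–20 alleles per locus).
    """

    n_genotypes: int = 72
    n_reps: int = 10
    mu: float = 10.0
    sigma2_g: float = 1.0
    sigma2_e: float = 1.0
    rep_effects: np.ndarray | None = None  # fixed; defaults to zeros

    # emergence-specific
    n_elevations: int = 3
    sigma2_al: float = 0.0
    n_groups: int = 4  # field-sampling groups
    group_resid_var: np.ndarray | None = None  # len n_groups; default homogeneous
    n_emergence_reps: int = 4
    seeds_per_box: int = 25
    inspection_interval: int = 2  # days between counts
    last_inspection_day: int = 30

    # growth-specific
    n_times: int = 5
    G_gm: np.ndarray | None = None  # t×t covariance of genotype-by-time effects
    time_effects: np.ndarray | None = None  # fixed; defaults to zeros
    time_resid_var: np.ndarray | None = None  # len n_times; default homogeneous

    # SSR-specific
    n_ssr_genotypes: int = 59
    n_loci: int = 8
    alleles_per_locus: tuple[int, ...] = (20, 9, 14, 8, 14, 19, 17, 17)
    allele_freqs: list[np.ndarray] | None = None  # default uniform per locus
    inbreeding: float | np.ndarray = 0.0  # global or per-locus F

    missing_rate: float = 0.0
    trait: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("need at least 2 genotypes")
        if self.n_reps < 2:
            raise ValueError("need at least 2 replicates")
        for name in ("sigma2_g", "sigma2_e", "sigma2_al"):
            _check_var(getattr(self, name), name)
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.group_resid_var is not None:
            arr = np.asarray(self.group_resid_var, dtype=float)
            if arr.shape != (self.n_groups,) or (arr < 0).any():
                raise ValueError("group_resid_var must be n_groups nonnegative variances")
        if self.time_resid_var is not None:
            arr = np.asarray(self.time_resid_var, dtype=float)
            if arr.shape != (self.n_times,) or (arr < 0).any():
                raise ValueError("time_resid_var must be n_times nonnegative variances")
        if self.G_gm is not None:
            g = np.asarray(self.G_gm, dtype=float)
            if g.shape != (self.n_times, self.n_times):
                raise ValueError(
                    f"G_gm must be {self.n_times}x{self.n_times} to match n_times, got {g.shape}"
                )
            _check_psd(g, "G_gm")


@dataclass
class TruthRecord:
    """Ground-truth parameters behind one simulated dataset."""

    trait: str = "trait"
    sigma2_g: float | None = None
    sigma2_al: float | None = None
    sigma2_e: float | dict[str, float] | None = None
    G_gm: np.ndarray | None = None
    genotype_effects: np.ndarray | None = None
    H2: float | None = None
    allele_freqs: list[np.ndarray] | None = None
    inbreeding: list[float] | None = None
    extras: dict = field(default_factory=dict)

    def to_flat(self) -> dict[str, float]:
        """Flatten to scalar key→value pairs for the plain-text writer."""
        out: dict[str, float] = {}
        for key in ("sigma2_g", "sigma2_al", "H2"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        if isinstance(self.sigma2_e, dict):
            for lvl, v in self.sigma2_e.items():
                out[f"sigma2_e.{lvl}"] = float(v)
        elif self.sigma2_e is not None:
            out["sigma2_e"] = float(self.sigma2_e)
        if self.G_gm is not None:
            g = np.asarray(self.G_gm)
            for i in range(g.shape[0]):
                for j in range(i, g.shape[1]):
                    out[f"G_gm.{i}.{j}"] = float(g[i, j])
        if self.genotype_effects is not None:
            for i, v in enumerate(np.asarray(self.genotype_effects)):
                out[f"g.{i}"] = float(v)
        if self.inbreeding is not None:
            for i, v in enumerate(self.inbreeding):
                out[f"F.{i}"] = float(v)
        if self.allele_freqs is not None:
            for i, p in enumerate(self.allele_freqs):
                for j, pj in enumerate(np.asarray(p)):
                    out[f"p.{i}.{j}"] = float(pj)
        for k, v in self.extras.items():
            out[k] = float(v)
        return out


def _genotype_labels(n: int) -> list[str]:
    return [f"G{i + 1:03d}" for i in range(n)]


def _apply_missing(table: pd.DataFrame, rate: float, rng: np.random.Generator) -> pd.DataFrame:
    if rate <= 0:
        return table
    keep = rng.random(len(table)) >= rate
    return table.loc[keep].reset_index(drop=True)


def simulate_biometric(config: SimulationConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """One trait under intercept + fixed replicates + IID genotype + IID residual.

    Returns a long-format phenotype table and the generating truth, including
    the plot-mean heritability sigma2_g / (sigma2_g + sigma2_e / r).
    """
    cfg = config
    rng = _rng(cfg.seed, "biometric")
    i, r = cfg.n_genotypes, cfg.n_reps
    rep_eff = np.zeros(r) if cfg.rep_effects is None else np.asarray(cfg.rep_effects, float)
    if rep_eff.shape != (r,):
        raise ValueError("rep_effects must have length n_reps")

    g = rng.normal(0.0, np.sqrt(cfg.sigma2_g), size=i)
    eps = rng.normal(0.0, np.sqrt(cfg.sigma2_e), size=(i, r))
    y = cfg.mu + rep_eff[None, :] + g[:, None] + eps

    labels = _genotype_labels(i)
    table = pd.DataFrame(
        {
            "genotype": np.repeat(labels, r),
            "group": "1",
            "replicate": np.tile(np.arange(1, r + 1), i),
            "elevation": "1",
            "eval_time": 0,
            "trait": cfg.trait,
            "value": y.ravel(),
        }
    )[PHENOTYPE_COLUMNS]
    table = _apply_missing(table, cfg.missing_rate, _rng(cfg.seed, "missing"))

    h2 = cfg.sigma2_g / (cfg.sigma2_g + cfg.sigma2_e / r) if (cfg.sigma2_g + cfg.sigma2_e) else 0.0
    truth = TruthRecord(
        trait=cfg.trait,
        sigma2_g=cfg.sigma2_g,
        sigma2_e=cfg.sigma2_e,
        genotype_effects=g,
        H2=h2,
    )
    return table, truth


def simulate_emergence(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TruthRecord, pd.DataFrame]:
    """Emergence trait with an elevation-class effect and per-group residuals.

    Genotypes are assigned round-robin to elevation classes and field-sampling
    groups. Besides the continuous phenotype table the generator emits per-box
    emergence count series (new emergents per inspection day, boxes of
    ``seeds_per_box`` seeds) for the derived-trait module.

    Returns ``(phenotypes, truth, counts)`` where ``counts`` has columns
    box, genotype, day, new_emergents, seeds_sown.
    """
    cfg = config
    if cfg.n_elevations < 2 and cfg.sigma2_al > 0:
        raise ValueError("simulating an elevation variance needs >= 2 elevation classes")
    if cfg.n_groups < 2:
        raise ValueError("need >= 2 field-sampling groups")
    rng = _rng(cfg.seed, "emergence")
    i, r = cfg.n_genotypes, cfg.n_emergence_reps

    elev_of = np.arange(i) % cfg.n_elevations
    group_of = np.arange(i) % cfg.n_groups
    gvar = (
        np.full(cfg.n_groups, cfg.sigma2_e)
        if cfg.group_resid_var is None
        else np.asarray(cfg.group_resid_var, float)
    )

    g = rng.normal(0.0, np.sqrt(cfg.sigma2_g), size=i)
    al = rng.normal(0.0, np.sqrt(cfg.sigma2_al), size=cfg.n_elevations)
    eps = rng.normal(0.0, 1.0, size=(i, r)) * np.sqrt(gvar[group_of])[:, None]
    y = cfg.mu + g[:, None] + al[elev_of][:, None] + eps

    labels = _genotype_labels(i)
    table = pd.DataFrame(
        {
            "genotype": np.repeat(labels, r),
            "group": np.repeat((group_of + 1).astype(str), r),
            "replicate": np.tile(np.arange(1, r + 1), i),
            "elevation": np.repeat((elev_of + 1).astype(str), r),
            "eval_time": 0,
            "trait": cfg.trait,
            "value": y.ravel(),
        }
    )[PHENOTYPE_COLUMNS]
    table = _apply_missing(table, cfg.missing_rate, _rng(cfg.seed, "missing"))

    # Per-box count series: emergence probability tied to the genotype effect,
    # timing spread around a genotype-specific mean day.
    days = np.arange(
        cfg.inspection_interval,
        cfg.last_inspection_day + 1,
        cfg.inspection_interval,
    )
    scale = np.sqrt(cfg.sigma2_g) if cfg.sigma2_g > 0 else 1.0
    rows = []
    box = 0
    for gi in range(i):
        p_emerge = 1.0 / (1.0 + np.exp(-(1.0 + g[gi] / scale)))
        mean_day = float(np.clip(10.0 - 2.0 * g[gi] / scale, days[0], days[-1]))
        w = np.exp(-0.5 * ((days - mean_day) / 4.0) ** 2)
        w /= w.sum()
        for _ in range(r):
            box += 1
            total = rng.binomial(cfg.seeds_per_box, p_emerge)
            counts = rng.multinomial(total, w)
            for d, c in zip(days, counts):
                rows.append((box, labels[gi], int(d), int(c), cfg.seeds_per_box))
    counts_df = pd.DataFrame(
        rows, columns=["box", "genotype", "day", "new_emergents", "seeds_sown"]
    )

    truth = TruthRecord(
        trait=cfg.trait,
        sigma2_g=cfg.sigma2_g,
        sigma2_al=cfg.sigma2_al,
        sigma2_e={str(k + 1): float(v) for k, v in enumerate(gvar)},
        genotype_effects=g,
    )
    return table, truth, counts_df


def simulate_growth(config: SimulationConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Growth trait with genotype-by-evaluation effects and per-time residuals.

    For each genotype a t-vector of interaction effects is drawn from
    N(0, G_gm); residual standard deviations may differ by evaluation time.
    """
    cfg = config
    if cfg.n_times < 2:
        raise ValueError("need >= 2 evaluation times")
    rng = _rng(cfg.seed, "growth")
    i, r, t = cfg.n_genotypes, cfg.n_reps, cfg.n_times

    G_gm = np.zeros((t, t)) if cfg.G_gm is None else np.asarray(cfg.G_gm, float)
    if G_gm.shape != (t, t):
        raise ValueError(f"G_gm must be {t}x{t}, got {G_gm.shape}")
    _check_psd(G_gm, "G_gm")
    tvar = (
        np.full(t, cfg.sigma2_e)
        if cfg.time_resid_var is None
        else np.asarray(cfg.time_resid_var, float)
    )
    time_eff = np.zeros(t) if cfg.time_effects is None else np.asarray(cfg.time_effects, float)
    rep_eff = np.zeros(r) if cfg.rep_effects is None else np.asarray(cfg.rep_effects, float)

    g = rng.normal(0.0, np.sqrt(cfg.sigma2_g), size=i)
    # gm[i] ~ N(0, G_gm); eigendecomposition handles PSD-but-singular matrices
    w, v = np.linalg.eigh(G_gm)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    gm = rng.normal(size=(i, t)) @ root.T
    eps = rng.normal(size=(i, r, t)) * np.sqrt(tvar)[None, None, :]

    y = (
        cfg.mu
        + rep_eff[None, :, None]
        + time_eff[None, None, :]
        + g[:, None, None]
        + gm[:, None, :]
        + eps
    )

    labels = _genotype_labels(i)
    idx = pd.MultiIndex.from_product(
        [labels, np.arange(1, r + 1), np.arange(1, t + 1)],
        names=["genotype", "replicate", "eval_time"],
    )
    table = idx.to_frame(index=False)
    table["group"] = "1"
    table["elevation"] = "1"
    table["trait"] = cfg.trait
    table["value"] = y.ravel()
    table = table[PHENOTYPE_COLUMNS]
    table = _apply_missing(table, cfg.missing_rate, _rng(cfg.seed, "missing"))

    truth = TruthRecord(
        trait=cfg.trait,
        sigma2_g=cfg.sigma2_g,
        sigma2_e={str(k + 1): float(v_) for k, v_ in enumerate(tvar)},
        G_gm=G_gm,
        genotype_effects=g,
    )
    return table, truth


def _feasible_F_lower(p: np.ndarray) -> float:
    # homozygote prob p_i^2 + F p_i (1 - p_i) >= 0  ⇔  F >= -p_i / (1 - p_i)
    p = p[p < 1.0]
    if p.size == 0:
        return -1.0
    return float(np.max(-p / (1.0 - p)))


def simulate_ssr(
    config: SimulationConfig, clip: bool = True
) -> tuple[pd.DataFrame, TruthRecord]:
    """Diploid SSR genotypes under per-locus allele frequencies and inbreeding F.

    Genotype probabilities: P(homozygote i) = p_i^2 + F p_i (1 - p_i),
    P(unordered heterozygote ij) = 2 p_i p_j (1 - F). Negative F (heterozygote
    excess) is supported down to the per-locus feasibility bound; an
    infeasible F is clipped with a warning naming the locus (``clip=True``,
    default) or raises (``clip=False``).

    Returns a genotype-by-locus table (two columns per locus, allele sizes in
    bp, NaN for missing) and the truth record.
    """
    cfg = config
    rng = _rng(cfg.seed, "ssr")
    n, L = cfg.n_ssr_genotypes, cfg.n_loci
    counts = list(cfg.alleles_per_locus)
    if len(counts) < L:
        raise ValueError("alleles_per_locus shorter than n_loci")
    counts = counts[:L]

    freqs: list[np.ndarray] = []
    if cfg.allele_freqs is not None:
        for k in range(L):
            p = np.asarray(cfg.allele_freqs[k], dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ValueError(f"allele frequencies at locus {k + 1} must sum to 1")
            freqs.append(p)
        counts = [len(p) for p in freqs]
    else:
        freqs = [np.full(a, 1.0 / a) for a in counts]

    F_in = np.asarray(cfg.inbreeding, dtype=float)
    F_per_locus = np.full(L, float(F_in)) if F_in.ndim == 0 else F_in
    if F_per_locus.shape != (L,):
        raise ValueError("inbreeding must be scalar or one value per locus")
    if (F_per_locus > 1).any() or (F_per_locus < -1).any():
        raise ValueError("inbreeding F must lie in [-1, 1]")

    loci = [f"L{k + 1:02d}" for k in range(L)]
    data: dict[str, np.ndarray] = {}
    F_used: list[float] = []
    for k, locus in enumerate(loci):
        p = freqs[k]
        a = len(p)
        sizes = 100 + 50 * k + 2 * np.arange(a)  # distinct bp ladders per locus
        F = float(F_per_locus[k])
        lo = _feasible_F_lower(p)
        if F < lo - 1e-12:
            if clip:
                warnings.warn(
                    f"inbreeding F={F:.3f} infeasible at locus {locus}; clipped to {lo:.3f}",
                    stacklevel=2,
                )
                F = lo
            else:
                raise ValueError(
                    f"inbreeding F={F:.3f} makes a genotype probability negative at locus {locus}"
                )
        F_used.append(F)

        # Unordered genotype distribution
        probs = []
        pairs = []
        for ii in range(a):
            probs.append(p[ii] ** 2 + F * p[ii] * (1 - p[ii]))
            pairs.append((ii, ii))
            for jj in range(ii + 1, a):
                probs.append(2 * p[ii] * p[jj] * (1 - F))
                pairs.append((ii, jj))
        probs = np.clip(np.asarray(probs), 0.0, None)
        probs /= probs.sum()
        draw = rng.choice(len(pairs), size=n, p=probs)
        a1 = np.array([sizes[pairs[d][0]] for d in draw], dtype=float)
        a2 = np.array([sizes[pairs[d][1]] for d in draw], dtype=float)
        if cfg.missing_rate > 0:
            miss = _rng(cfg.seed, "missing").random(n) < cfg.missing_rate
            a1[miss] = np.nan
            a2[miss] = np.nan
        data[f"{locus}.a"] = a1
        data[f"{locus}.b"] = a2

    table = pd.DataFrame(data, index=pd.Index(_genotype_labels(n), name="genotype"))
    truth = TruthRecord(allele_freqs=freqs, inbreeding=F_used)
    return table, truth


def simulate_clustered_panel(
    n_clusters: int = 3,
    genotypes_per_cluster: int = 20,
    n_traits: int = 3,
    separation: float = 8.0,
    n_loci: int = 8,
    alleles_per_cluster: int = 5,
    major_allele_freq: float = 0.8,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Panel with planted cluster structure in both trait and SSR space.

    Emulates a germplasm collection whose genotypes come from a few strongly
    differentiated origins: cluster trait means sit ``separation``
    within-cluster SDs apart along distinct axes (every trait carries
    between-cluster signal, so SD standardization keeps the contrast), and
    each cluster draws its SSR alleles from a disjoint size block per locus
    with a skewed frequency profile (complete molecular differentiation with
    modest within-origin variation). Intended for recovery tests of the
    fused-distance clustering pipeline.

    Returns ``(trait_matrix, ssr_table, true_cluster)`` where ``trait_matrix``
    is genotypes × traits (the shape of a BLUP matrix) and ``true_cluster``
    maps genotype label → planted cluster id.
    """
    rng = _rng(seed, "clustered")
    n = n_clusters * genotypes_per_cluster
    labels = _genotype_labels(n)
    cluster = np.repeat(np.arange(n_clusters), genotypes_per_cluster)

    means = np.zeros((n_clusters, n_traits))
    for c in range(n_clusters):
        means[c, c % n_traits] = separation * (1 + c // n_traits)
    traits = means[cluster] + rng.normal(size=(n, n_traits))
    trait_df = pd.DataFrame(
        traits,
        index=pd.Index(labels, name="genotype"),
        columns=[f"T{j + 1}" for j in range(n_traits)],
    )

    # Per cluster and locus, alleles come from a disjoint size block with a
    # skewed frequency profile (a common major allele), the pattern of
    # strongly differentiated origins: between-cluster similarity is zero
    # while within-cluster pairs mostly share the major allele.
    data: dict[str, np.ndarray] = {}
    for k in range(n_loci):
        a1 = np.empty(n)
        a2 = np.empty(n)
        for c in range(n_clusters):
            sizes = 100 + 100 * k + 20 * c + 2 * np.arange(alleles_per_cluster)
            minor = (1.0 - major_allele_freq) / max(alleles_per_cluster - 1, 1)
            freqs = np.full(alleles_per_cluster, minor)
            freqs[0] = major_allele_freq
            freqs /= freqs.sum()
            sel = cluster == c
            m = sel.sum()
            a1[sel] = rng.choice(sizes, size=m, p=freqs)
            a2[sel] = rng.choice(sizes, size=m, p=freqs)
        data[f"L{k + 1:02d}.a"] = a1
        data[f"L{k + 1:02d}.b"] = a2
    ssr = pd.DataFrame(data, index=pd.Index(labels, name="genotype"))

    true = pd.Series(cluster + 1, index=pd.Index(labels, name="genotype"), name="cluster")
    return trait_df, ssr, true
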