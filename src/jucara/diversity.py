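"""Per-locus diversity statistics for diploid codominant SSR markers.

Works on genotype-by-locus tables of allele sizes (bp) with two columns per
locus (``<locus>.a``, ``<locus>.b``) and NaN for missing calls. Allele
frequencies are computed per locus from genotyped individuals only, matching
the varying per-locus sample sizes of partially genotyped panels.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def locus_names(table: pd.DataFrame) -> list[str]:
    """Locus labels from a two-columns-per-locus table."""
    names = []
    for col in table.columns:
        if col.endswith(".a"):
            locus = col[:-2]
            if f"{locus}.b" not in table.columns:
                raise ValueError(f"locus {locus} missing its second allele column")
            names.append(locus)
    if not names:
        raise ValueError("no locus columns found (expected '<locus>.a'/'<locus>.b')")
    return names


def _calls(table: pd.DataFrame, locus: str) -> np.ndarray:
    """Complete diploid calls at a locus: (N, 2) array of allele sizes."""
    a = table[f"{locus}.a"].to_numpy(float)
    b = table[f"{locus}.b"].to_numpy(float)
    ok = np.isfinite(a) & np.isfinite(b)
    return np.column_stack([a[ok], b[ok]])


def allele_frequencies(table: pd.DataFrame, locus: str) -> pd.Series:
    """Allele frequencies from the 2N observed allele copies at a locus."""
    calls = _calls(table, locus)
    if calls.size == 0:
        return pd.Series(dtype=float)
    alleles, counts = np.unique(calls.ravel(), return_counts=True)
    return pd.Series(counts / counts.sum(), index=alleles.astype(int))


def observed_heterozygosity(table: pd.DataFrame, locus: str) -> float:
    """Fraction of genotyped individuals that are heterozygous at the locus."""
    calls = _calls(table, locus)
    if calls.shape[0] == 0:
        log.warning("locus %s has no genotyped individuals", locus)
        return float("nan")
    return float(np.mean(calls[:, 0] != calls[:, 1]))


def expected_heterozygosity(table: pd.DataFrame, locus: str) -> float:
    """Unbiased expected heterozygosity: N/(N-1) · (1 - Σ p_i²)."""
    calls = _calls(table, locus)
    n = calls.shape[0]
    if n < 2:
        return float("nan")
    p = allele_frequencies(table, locus).to_numpy()
    return float(n / (n - 1.0) * (1.0 - np.sum(p**2)))


def inbreeding_coefficient(ho: float, he: float) -> float:
    """F = 1 - Ho/He; NaN for a monomorphic locus (He = 0).

    Negative values indicate heterozygote excess.
    """
    if not np.isfinite(he) or he == 0:
        return float("nan")
    return float(1.0 - ho / he)


def pic(table_or_freqs: pd.DataFrame | np.ndarray | pd.Series, locus: str | None = None) -> float:
    """Polymorphic information content: 1 - Σ p_i² - Σ_{i≠j} p_i² p_j².

    The cross term runs over ordered pairs i≠j, i.e. 2·Σ_{i<j} p_i² p_j².
    Accepts either a genotype table plus locus name or a frequency vector.
    """
    if isinstance(table_or_freqs, pd.DataFrame) and locus is not None:
        p = allele_frequencies(table_or_freqs, locus).to_numpy()
    else:
        p = np.asarray(table_or_freqs, dtype=float)
    if p.size == 0:
        return float("nan")
    p2 = p**2
    s2 = p2.sum()
    cross = s2**2 - np.sum(p2**2)  # ordered-pair double sum over i != j
    return float(1.0 - s2 - cross)


def summarize_loci(table: pd.DataFrame) -> pd.DataFrame:
    """Per-locus N, N_A, Ho, He, F and PIC, plus a 'mean' row.

    The mean row carries the across-locus mean N_A and mean PIC (the overall
    summaries reported for diversity panels); other columns of the mean row
    are across-locus means as well, except F which is left to per-locus
    interpretation (mean of defined values).
    """
    rows = []
    for locus in locus_names(table):
        calls = _calls(table, locus)
        n = calls.shape[0]
        if n == 0:
            log.warning("locus %s skipped: all calls missing", locus)
            rows.append((locus, 0, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        freqs = allele_frequencies(table, locus)
        ho = observed_heterozygosity(table, locus)
        he = expected_heterozygosity(table, locus)
        f = inbreeding_coefficient(ho, he)
        rows.append((locus, n, len(freqs), ho, he, f, pic(freqs.to_numpy())))
    out = pd.DataFrame(rows, columns=["locus", "N", "N_A", "Ho", "He", "F", "PIC"])
    mean = {
        "locus": "mean",
        "N": out["N"].mean(),
        "N_A": out["N_A"].mean(),
        "Ho": out["Ho"].mean(),
        "He": out["He"].mean(),
        "F": out["F"].mean(),
        "PIC": out["PIC"].mean(),
    }
    return pd.concat([out, pd.DataFrame([mean])], ignore_index=True)
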