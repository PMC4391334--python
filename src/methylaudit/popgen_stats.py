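"""Per-probe population-genetic summaries.

Genotype counts are over the two-allele system (C, D) where D stands for the
unidentified non-C base at the assayed CpG. The Hardy-Weinberg test is a
Pearson chi-square with 1 degree of freedom against expected counts
(n*p^2, 2n*p*q, n*q^2), no continuity correction; monomorphic probes are
assigned chi2 = 0, p = 1 by convention (they carry no testable signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    InsufficientDataError,
    InsufficientVarianceError,
    UndefinedStatisticError,
)


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of called genotypes at one probe."""

    n_cc: int
    n_cd: int
    n_dd: int

    def __post_init__(self) -> None:
        if min(self.n_cc, self.n_cd, self.n_dd) < 0:
            raise ValueError("genotype counts must be non-negative")

    @property
    def n_total(self) -> int:
        return self.n_cc + self.n_cd + self.n_dd


@dataclass(frozen=True)
class ProbeGenotypeSummary:
    """One probe's genotype counts plus derived population statistics."""

    probe_id: str
    counts: GenotypeCounts
    maf: float
    het_obs: float
    het_exp: float
    hwe_chi2: float
    hwe_p: float
    n_missing: int = 0


def allele_frequencies(counts: GenotypeCounts) -> tuple[float, float]:
    """Return (f_C, f_D) from genotype counts by allele counting."""
    n = counts.n_total
    if n == 0:
        raise UndefinedStatisticError("allele frequencies undefined for 0 calls")
    f_c = (2 * counts.n_cc + counts.n_cd) / (2 * n)
    return f_c, 1.0 - f_c


def minor_allele_frequency(counts: GenotypeCounts) -> float:
    """Frequency of the rarer allele, in [0, 0.5]."""
    f_c, f_d = allele_frequencies(counts)
    return min(f_c, f_d)


def observed_heterozygosity(counts: GenotypeCounts) -> float:
    """Fraction of called individuals that are heterozygous."""
    n = counts.n_total
    if n == 0:
        raise UndefinedStatisticError(
            "observed heterozygosity undefined for 0 calls"
        )
    return counts.n_cd / n


def expected_heterozygosity(counts: GenotypeCounts) -> float:
    """HWE-expected heterozygosity 2*p*q, in [0, 0.5]."""
    f_c, f_d = allele_frequencies(counts)
    return 2.0 * f_c * f_d


def hwe_test(counts: GenotypeCounts) -> tuple[float, float]:
    """Pearson chi-square test of Hardy-Weinberg proportions.

    Returns ``(chi2, p)`` with 1 df and no continuity correction. Monomorphic
    counts (one allele absent) return ``(0.0, 1.0)``.
    """
    n = counts.n_total
    if n == 0:
        raise UndefinedStatisticError("HWE test undefined for 0 calls")
    f_c, f_d = allele_frequencies(counts)
    if f_c == 0.0 or f_d == 0.0:
        return 0.0, 1.0
    expected = np.array([n * f_c**2, 2 * n * f_c * f_d, n * f_d**2])
    observed = np.array([counts.n_cc, counts.n_cd, counts.n_dd], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, p


def hwe_test_arrays(
    n_cc: np.ndarray, n_cd: np.ndarray, n_dd: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized HWE chi-square over parallel count arrays.

    Same convention as :func:`hwe_test`; positions with zero total or a
    missing allele get chi2 = 0, p = 1.
    """
    n_cc = np.asarray(n_cc, dtype=float)
    n_cd = np.asarray(n_cd, dtype=float)
    n_dd = np.asarray(n_dd, dtype=float)
    n = n_cc + n_cd + n_dd
    with np.errstate(divide="ignore", invalid="ignore"):
        f_c = (2 * n_cc + n_cd) / (2 * n)
    f_d = 1.0 - f_c
    polymorphic = (n > 0) & (f_c > 0) & (f_d > 0)
    chi2 = np.zeros_like(n)
    exp_cc = n * f_c**2
    exp_cd = 2 * n * f_c * f_d
    exp_dd = n * f_d**2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (
            (n_cc - exp_cc) ** 2 / exp_cc
            + (n_cd - exp_cd) ** 2 / exp_cd
            + (n_dd - exp_dd) ** 2 / exp_dd
        )
    chi2[polymorphic] = terms[polymorphic]
    p = np.ones_like(n)
    p[polymorphic] = stats.chi2.sf(chi2[polymorphic], df=1)
    return chi2, p


def summarize_counts(
    probe_id: str, counts: GenotypeCounts, n_missing: int = 0
) -> ProbeGenotypeSummary:
    """Assemble the full per-probe summary from raw genotype counts."""
    chi2, p = hwe_test(counts)
    return ProbeGenotypeSummary(
        probe_id=probe_id,
        counts=counts,
        maf=minor_allele_frequency(counts),
        het_obs=observed_heterozygosity(counts),
        het_exp=expected_heterozygosity(counts),
        hwe_chi2=chi2,
        hwe_p=p,
        n_missing=n_missing,
    )


def compare_heterozygosity(
    summaries: list[ProbeGenotypeSummary],
    reference: dict[str, float] | pd.Series,
) -> tuple[pd.DataFrame, float, list[str]]:
    """Join observed against reference heterozygosity and correlate.

    Parameters
    ----------
    summaries:
        Per-probe summaries (observed heterozygosity is taken from each).
    reference:
        Mapping probe_id -> reference heterozygosity (e.g. genome-browser
        values).

    Returns
    -------
    (table, r, absent)
        ``table`` has columns probe_id, het_obs, het_ref, difference over the
        shared probes; ``r`` is the Pearson correlation; ``absent`` lists
        probe IDs with no reference entry (reported, never silently dropped).
    """
    ref = pd.Series(reference, dtype=float)
    shared_rows = []
    absent: list[str] = []
    for s in summaries:
        if s.probe_id in ref.index:
            shared_rows.append((s.probe_id, s.het_obs, float(ref[s.probe_id])))
        else:
            absent.append(s.probe_id)
    if len(shared_rows) < 2:
        raise InsufficientDataError(
            f"need >= 2 probes shared with the reference, got {len(shared_rows)}"
        )
    table = pd.DataFrame(shared_rows, columns=["probe_id", "het_obs", "het_ref"])
    table["difference"] = table["het_obs"] - table["het_ref"]
    if table["het_obs"].nunique() < 2 or table["het_ref"].nunique() < 2:
        raise InsufficientVarianceError(
            "correlation undefined: observed or reference column is constant"
        )
    r = float(stats.pearsonr(table["het_obs"], table["het_ref"]).statistic)
    return table, r, absent


def summaries_to_frame(summaries: list[ProbeGenotypeSummary]) -> pd.DataFrame:
    """Flatten summaries to the tabular report schema used by the CLI."""
    return pd.DataFrame(
        [
            {
                "probe_id": s.probe_id,
                "n_CC": s.counts.n_cc,
                "n_CD": s.counts.n_cd,
                "n_DD": s.counts.n_dd,
                "n_missing": s.n_missing,
                "maf": s.maf,
                "het_obs": s.het_obs,
                "het_exp": s.het_exp,
                "hwe_chi2": s.hwe_chi2,
                "hwe_p": s.hwe_p,
            }
            for s in summaries
        ],
        columns=[
            "probe_id",
            "n_CC",
            "n_CD",
            "n_DD",
            "n_missing",
            "maf",
            "het_obs",
            "het_exp",
            "hwe_chi2",
            "hwe_p",
        ],
    )
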