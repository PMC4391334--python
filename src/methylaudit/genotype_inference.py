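"""Tri-modal binning of beta values, candidacy filtering and genotype calling.

Beta values are binned as X (> 0.7), Y (0.3-0.7, exclusive) and Z (< 0.25);
values falling on a boundary or in the 0.25-0.3 gap are *unbinned* and later
treated as missing calls. Bins map to genotypes X -> CC, Y -> CD, Z -> DD,
where D is the unidentified non-C allele at the assayed CpG: a heterozygote
loses half the methylation signal, a D homozygote loses all of it.

A probe is a genotyping candidate when at least ``min_binned_fraction`` of
its samples fall in one of the three bins (ceil(fraction * n_samples),
i.e. 106 of 111 at the default 95%) and each homozygote bin (X and Z) holds
at least ``min_homozygote_count`` samples. Candidates are then screened by a
Hardy-Weinberg equilibrium test on the inferred genotype counts; probes with
HWE P above ``hwe_p_min`` are retained and ranked by observed
heterozygosity, descending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import BetaDomainError, UnknownIDError
from .io_methylation import BetaMatrix, GenotypeCallMatrix, genotype_matrix_from_arrays
from .popgen_stats import (
    GenotypeCounts,
    ProbeGenotypeSummary,
    hwe_test_arrays,
    summarize_counts,
)

BIN_X = "X"
BIN_Y = "Y"
BIN_Z = "Z"
UNBINNED = "unbinned"
MISSING = "missing"

BIN_TO_GENOTYPE = {BIN_X: "CC", BIN_Y: "CD", BIN_Z: "DD"}


@dataclass(frozen=True)
class BinThresholds:
    """Bin boundaries (all strict inequalities)."""

    x_min: float = 0.7
    y_low: float = 0.3
    y_high: float = 0.7
    z_max: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.z_max <= self.y_low <= self.y_high <= self.x_min <= 1.0:
            raise ValueError(
                "thresholds must satisfy 0 <= z_max <= y_low <= y_high <= x_min <= 1"
            )


@dataclass(frozen=True)
class BinProfile:
    """Bin occupancy counts for one probe row."""

    n_x: int
    n_y: int
    n_z: int
    n_unbinned: int
    n_missing: int

    @property
    def n_binned(self) -> int:
        return self.n_x + self.n_y + self.n_z

    @property
    def n_samples(self) -> int:
        return self.n_binned + self.n_unbinned + self.n_missing


@dataclass(frozen=True)
class CandidacyParams:
    """Filter parameters for genotyping-candidate probes."""

    min_binned_fraction: float = 0.95
    min_homozygote_count: int = 4
    hwe_p_min: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.min_binned_fraction <= 1.0:
            raise ValueError("min_binned_fraction must lie in (0, 1]")
        if self.min_homozygote_count < 0:
            raise ValueError("min_homozygote_count must be non-negative")
        if not 0.0 <= self.hwe_p_min < 1.0:
            raise ValueError("hwe_p_min must lie in [0, 1)")


def min_binned_count(n_samples: int, min_binned_fraction: float = 0.95) -> int:
    """Smallest binned-sample count satisfying the coverage rule.

    ``ceil(fraction * n_samples)``; 106 for the default 95% of 111 samples.
    """
    return math.ceil(min_binned_fraction * n_samples)


def assign_bin(
    beta: float | None, thresholds: BinThresholds = BinThresholds()
) -> str:
    """Assign one beta value to X / Y / Z / unbinned / missing.

    Exactly one label applies to any value in [0, 1]; boundary values are
    unbinned because all bin inequalities are strict.
    """
    if beta is None or (isinstance(beta, float) and math.isnan(beta)):
        return MISSING
    if not 0.0 <= beta <= 1.0:
        raise BetaDomainError(f"beta value {beta} outside [0, 1]")
    if beta > thresholds.x_min:
        return BIN_X
    if thresholds.y_low < beta < thresholds.y_high:
        return BIN_Y
    if beta < thresholds.z_max:
        return BIN_Z
    return UNBINNED


def _bin_masks(
    values: np.ndarray, thresholds: BinThresholds
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Boolean masks (x, y, z, missing) over a float array; NaN-safe."""
    with np.errstate(invalid="ignore"):
        if ((values < 0.0) | (values > 1.0)).any():
            bad = values[(values < 0.0) | (values > 1.0)][0]
            raise BetaDomainError(f"beta value {bad} outside [0, 1]")
        x = values > thresholds.x_min
        y = (values > thresholds.y_low) & (values < thresholds.y_high)
        z = values < thresholds.z_max
    return x, y, z, np.isnan(values)


def bin_profile(
    probe_row: Sequence[float], thresholds: BinThresholds = BinThresholds()
) -> BinProfile:
    """Count bin occupancies for one probe's beta values."""
    values = np.asarray(probe_row, dtype=float)
    if values.size == 0:
        raise ValueError("probe row must be nonempty")
    x, y, z, missing = _bin_masks(values, thresholds)
    n_x, n_y, n_z = int(x.sum()), int(y.sum()), int(z.sum())
    n_missing = int(missing.sum())
    return BinProfile(
        n_x=n_x,
        n_y=n_y,
        n_z=n_z,
        n_unbinned=values.size - n_x - n_y - n_z - n_missing,
        n_missing=n_missing,
    )


def passes_candidacy(
    profile: BinProfile,
    n_samples: int,
    params: CandidacyParams = CandidacyParams(),
) -> tuple[bool, str]:
    """Apply the bin-coverage and homozygote-count rules.

    Returns ``(ok, reason)``; ``reason`` names the first failed rule, or is
    empty when the probe passes.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    threshold = min_binned_count(n_samples, params.min_binned_fraction)
    if profile.n_binned < threshold:
        return False, (
            f"binned-fraction: {profile.n_binned} binned < required {threshold}"
        )
    if profile.n_x < params.min_homozygote_count:
        return False, (
            f"homozygote-X count: {profile.n_x} < {params.min_homozygote_count}"
        )
    if profile.n_z < params.min_homozygote_count:
        return False, (
            f"homozygote-Z count: {profile.n_z} < {params.min_homozygote_count}"
        )
    return True, ""


def call_genotypes(
    matrix: BetaMatrix,
    probes: Sequence[str] | None = None,
    thresholds: BinThresholds = BinThresholds(),
) -> GenotypeCallMatrix:
    """Convert beta values to genotype calls for a probe subset.

    X -> CC, Y -> CD, Z -> DD; unbinned and missing betas become missing
    calls. ``probes=None`` calls every probe in the matrix.
    """
    if probes is None:
        probe_list = matrix.probe_ids
    else:
        probe_list = list(probes)
        unknown = [p for p in probe_list if p not in matrix.data.index]
        if unknown:
            raise UnknownIDError(f"unknown probe IDs: {unknown[:5]}")
    values = matrix.data.loc[probe_list].to_numpy(dtype=float)
    values = values.reshape(len(probe_list), matrix.n_samples)
    x, y, z, _ = _bin_masks(values, thresholds)
    calls = np.full(values.shape, np.nan, dtype=object)
    calls[x] = "CC"
    calls[y] = "CD"
    calls[z] = "DD"
    return genotype_matrix_from_arrays(probe_list, matrix.sample_ids, calls)


def select_informative_probes(
    matrix: BetaMatrix,
    params: CandidacyParams = CandidacyParams(),
    thresholds: BinThresholds = BinThresholds(),
) -> list[ProbeGenotypeSummary]:
    """End-to-end informative-probe discovery.

    Pipeline: bin every probe, keep candidacy-passing probes, convert bins to
    genotype counts, run the HWE test, retain probes with HWE P strictly
    above ``params.hwe_p_min``. The result is sorted by observed
    heterozygosity descending, ties broken by probe ID ascending.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    values = matrix.values()
    x, y, z, _ = _bin_masks(values, thresholds)
    n_x = x.sum(axis=1)
    n_y = y.sum(axis=1)
    n_z = z.sum(axis=1)
    threshold = min_binned_count(matrix.n_samples, params.min_binned_fraction)
    candidate = (
        (n_x + n_y + n_z >= threshold)
        & (n_x >= params.min_homozygote_count)
        & (n_z >= params.min_homozygote_count)
    )
    idx = np.flatnonzero(candidate)
    if idx.size == 0:
        return []
    chi2, p = hwe_test_arrays(n_x[idx], n_y[idx], n_z[idx])
    keep = p > params.hwe_p_min
    summaries = []
    probe_ids = matrix.data.index
    for j, k in enumerate(idx):
        if not keep[j]:
            continue
        counts = GenotypeCounts(int(n_x[k]), int(n_y[k]), int(n_z[k]))
        summaries.append(
            summarize_counts(
                str(probe_ids[k]),
                counts,
                n_missing=matrix.n_samples - counts.n_total,
            )
        )
    summaries.sort(key=lambda s: (-s.het_obs, s.probe_id))
    return summaries


def top_k(
    summaries: list[ProbeGenotypeSummary], k: int
) -> list[ProbeGenotypeSummary]:
    """First ``k`` entries of an already-ranked summary list."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    return summaries[:k]
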