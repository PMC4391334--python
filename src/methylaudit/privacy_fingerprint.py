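"""Sample fingerprints, cross-dataset matching and probe redaction.

A fingerprint is one sample's ordered genotype vector over a chosen set of
informative loci. Matching compares two fingerprints over the loci called in
both; the evidence that a match is non-coincidental is quantified by the
forensic product rule under Hardy-Weinberg proportions and locus
independence (reported as log10 of the random-match probability — linked
CpG loci violate independence, so treat the number as an approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import math

import numpy as np
import pandas as pd

from .errors import (
    DegenerateLocusError,
    InsufficientOverlapError,
    UnknownIDError,
)
from .io_methylation import BetaMatrix, GenotypeCallMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Fingerprint:
    """One sample's genotype calls over an ordered locus list.

    ``calls[i]`` is the call at ``loci[i]``: one of "CC", "CD", "DD" or None
    for missing.
    """

    sample_id: str
    loci: tuple[str, ...]
    calls: tuple[str | None, ...]

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.loci):
            raise ValueError("calls and loci must have equal length")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("fingerprint loci must be unique")

    def __len__(self) -> int:
        return len(self.loci)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of comparing two fingerprints."""

    n_compared: int
    n_concordant: int
    concordance: float
    random_match_log10p: float | None = None


@dataclass(frozen=True)
class RedactionResult:
    """Outcome of removing probes from a beta matrix."""

    matrix: BetaMatrix
    n_removed: int
    absent_probes: tuple[str, ...]


def _as_call(value: object) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return str(value)


def build_fingerprint(
    calls: GenotypeCallMatrix, sample_id: str, loci: Sequence[str]
) -> Fingerprint:
    """Extract one sample's calls in the given locus order (missing kept)."""
    if sample_id not in calls.data.columns:
        raise UnknownIDError(f"unknown sample ID {sample_id!r}")
    unknown = [p for p in loci if p not in calls.data.index]
    if unknown:
        raise UnknownIDError(f"unknown locus IDs: {unknown[:5]}")
    if len(loci) == 0:
        logger.warning("building an empty fingerprint for sample %s", sample_id)
        return Fingerprint(sample_id, (), ())
    column = calls.data.loc[list(loci), sample_id]
    return Fingerprint(
        sample_id=sample_id,
        loci=tuple(loci),
        calls=tuple(_as_call(v) for v in column),
    )


def concordance(a: Fingerprint, b: Fingerprint) -> MatchResult:
    """Fraction of loci, called in both fingerprints, with identical calls.

    Symmetric in its arguments. Loci missing in either fingerprint are
    excluded from the denominator.
    """
    shared = [locus for locus in a.loci if locus in set(b.loci)]
    if not shared:
        raise InsufficientOverlapError(
            f"fingerprints {a.sample_id!r} and {b.sample_id!r} share no loci"
        )
    a_map = dict(zip(a.loci, a.calls))
    b_map = dict(zip(b.loci, b.calls))
    n_compared = 0
    n_concordant = 0
    for locus in shared:
        ca, cb = a_map[locus], b_map[locus]
        if ca is None or cb is None:
            continue
        n_compared += 1
        if ca == cb:
            n_concordant += 1
    if n_compared == 0:
        raise InsufficientOverlapError(
            f"fingerprints {a.sample_id!r} and {b.sample_id!r} have no loci "
            "non-missing in both"
        )
    return MatchResult(
        n_compared=n_compared,
        n_concordant=n_concordant,
        concordance=n_concordant / n_compared,
    )


def random_match_probability(
    fp: Fingerprint, freqs: Mapping[str, float]
) -> float:
    """log10 probability that a random individual shows this profile.

    Product rule under HWE: each non-missing locus contributes
    log10 of the genotype frequency of the observed call (CC -> f_C^2,
    CD -> 2*f_C*f_D, DD -> f_D^2), with ``freqs`` giving the D-allele
    frequency per locus. Missing-call loci are skipped (and logged).
    """
    total = 0.0
    n_skipped = 0
    n_used = 0
    for locus, call in zip(fp.loci, fp.calls):
        if call is None:
            n_skipped += 1
            continue
        if locus not in freqs:
            raise UnknownIDError(f"no allele frequency for locus {locus!r}")
        f_d = float(freqs[locus])
        if not 0.0 < f_d < 1.0:
            raise DegenerateLocusError(
                f"locus {locus!r} has degenerate D-allele frequency {f_d}"
            )
        f_c = 1.0 - f_d
        if call == "CC":
            g = f_c * f_c
        elif call == "CD":
            g = 2.0 * f_c * f_d
        elif call == "DD":
            g = f_d * f_d
        else:
            raise ValueError(f"invalid call {call!r} at locus {locus!r}")
        total += math.log10(g)
        n_used += 1
    if n_skipped:
        logger.info(
            "random_match_probability: %d of %d loci skipped (missing calls)",
            n_skipped,
            len(fp),
        )
    if n_used == 0:
        logger.warning("random_match_probability over 0 usable loci: log10 P = 0")
    return total


def match_samples(
    query: GenotypeCallMatrix,
    reference: GenotypeCallMatrix,
    min_overlap: int = 30,
    freqs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Score every query x reference sample pair by genotype concordance.

    Returns a table (query_sample, reference_sample, n_compared,
    n_concordant, concordance[, random_match_log10p]) ranked by concordance
    descending. Pairs with fewer than ``min_overlap`` loci non-missing in
    both are omitted; the omitted count is logged.
    """
    shared = [p for p in query.data.index if p in set(reference.data.index)]
    if not shared:
        raise InsufficientOverlapError("query and reference share no loci")

    def codes(matrix: GenotypeCallMatrix) -> np.ndarray:
        frame = matrix.data.loc[shared]
        mapping = {"CC": 0, "CD": 1, "DD": 2}
        arr = frame.to_numpy(dtype=object)
        out = np.full(arr.shape, -1, dtype=np.int8)
        for call, code in mapping.items():
            out[arr == call] = code
        return out

    q = codes(query)
    r = codes(reference)
    rows = []
    n_omitted = 0
    for i, qs in enumerate(query.data.columns):
        for j, rs in enumerate(reference.data.columns):
            both = (q[:, i] >= 0) & (r[:, j] >= 0)
            n_compared = int(both.sum())
            if n_compared < min_overlap:
                n_omitted += 1
                continue
            n_conc = int((q[both, i] == r[both, j]).sum())
            row = {
                "query_sample": qs,
                "reference_sample": rs,
                "n_compared": n_compared,
                "n_concordant": n_conc,
                "concordance": n_conc / n_compared,
            }
            if freqs is not None:
                fp = build_fingerprint(
                    reference, rs, [shared[k] for k in np.flatnonzero(both)]
                )
                row["random_match_log10p"] = random_match_probability(fp, freqs)
            rows.append(row)
    if n_omitted:
        logger.warning(
            "match_samples: %d pairs omitted (overlap < %d)", n_omitted, min_overlap
        )
    columns = [
        "query_sample",
        "reference_sample",
        "n_compared",
        "n_concordant",
        "concordance",
    ]
    if freqs is not None:
        columns.append("random_match_log10p")
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(
        ["concordance", "n_compared"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)


def redact_probes(
    matrix: BetaMatrix, probes: Sequence[str]
) -> RedactionResult:
    """Remove listed probes from a beta matrix (samples untouched).

    Absent probe IDs are tolerated and reported in the result; removal, not
    masking, so no trace of the redacted rows remains.
    """
    probe_set = set(probes)
    present = [p for p in matrix.data.index if p in probe_set]
    absent = tuple(p for p in dict.fromkeys(probes) if p not in matrix.data.index)
    if absent:
        logger.warning(
            "redact_probes: %d listed probes absent from matrix", len(absent)
        )
    redacted = BetaMatrix(matrix.data.drop(index=present))
    return RedactionResult(
        matrix=redacted, n_removed=len(present), absent_probes=absent
    )
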