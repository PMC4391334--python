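"""Trait-associated CpG extraction and substance-use flagging.

The default panel holds the one locus with solid support here: cg05575921
(AHRR), whose methylation drops with smoking. No default threshold ships —
the tool refuses to invent clinical cutoffs, so flagging requires an
explicit, user-supplied threshold which is recorded in the report header.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ConfigurationError
from .io_methylation import BetaMatrix

logger = logging.getLogger(__name__)

LOWER_IN_POSITIVE = "lower_in_positive"
HIGHER_IN_POSITIVE = "higher_in_positive"

POSITIVE = "positive"
NEGATIVE = "negative"
INDETERMINATE = "indeterminate"

SMOKING_PROBE_ID = "cg05575921"


@dataclass(frozen=True)
class TraitProbe:
    """A CpG whose methylation tracks a trait."""

    probe_id: str
    trait_label: str
    direction: str = LOWER_IN_POSITIVE
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in (LOWER_IN_POSITIVE, HIGHER_IN_POSITIVE):
            raise ConfigurationError(
                f"direction must be {LOWER_IN_POSITIVE!r} or "
                f"{HIGHER_IN_POSITIVE!r}, got {self.direction!r}"
            )
        if self.threshold is not None and not 0.0 <= self.threshold <= 1.0:
            raise ConfigurationError(
                f"threshold must lie in [0, 1], got {self.threshold}"
            )


def default_panel() -> list[TraitProbe]:
    """The shipped panel: smoking via cg05575921, threshold unset."""
    return [
        TraitProbe(
            probe_id=SMOKING_PROBE_ID,
            trait_label="smoking",
            direction=LOWER_IN_POSITIVE,
        )
    ]


def extract_trait_betas(
    matrix: BetaMatrix, panel: Sequence[TraitProbe]
) -> tuple[pd.DataFrame, list[TraitProbe]]:
    """Pull per-sample beta values for each panel probe present.

    Returns ``(table, not_assayed)``: one table row per (sample, present
    panel probe) with missing betas kept as NaN, and the list of panel
    probes absent from the matrix.
    """
    if len(panel) == 0:
        logger.warning("extract_trait_betas called with an empty panel")
    rows = []
    not_assayed: list[TraitProbe] = []
    for probe in panel:
        if probe.probe_id not in matrix.data.index:
            not_assayed.append(probe)
            continue
        betas = matrix.data.loc[probe.probe_id]
        for sample_id, beta in betas.items():
            rows.append(
                {
                    "sample_id": sample_id,
                    "probe_id": probe.probe_id,
                    "trait": probe.trait_label,
                    "beta": beta,
                }
            )
    table = pd.DataFrame(rows, columns=["sample_id", "probe_id", "trait", "beta"])
    if not_assayed:
        logger.warning(
            "panel probes not assayed: %s", [p.probe_id for p in not_assayed]
        )
    return table, not_assayed


def flag_trait_status(beta: float | None, probe: TraitProbe) -> str:
    """Flag one beta value as positive / negative / indeterminate.

    For ``lower_in_positive``: beta < threshold -> positive, beta >=
    threshold -> negative; mirrored for ``higher_in_positive``. Missing beta
    is indeterminate.
    """
    if probe.threshold is None:
        raise ConfigurationError(
            f"no threshold set for {probe.probe_id} ({probe.trait_label}); "
            "supply one explicitly — no default cutoff ships"
        )
    if beta is None or (isinstance(beta, float) and math.isnan(beta)):
        return INDETERMINATE
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta value {beta} outside [0, 1]")
    if probe.direction == LOWER_IN_POSITIVE:
        return POSITIVE if beta < probe.threshold else NEGATIVE
    return POSITIVE if beta > probe.threshold else NEGATIVE


def flag_report(
    matrix: BetaMatrix, panel: Sequence[TraitProbe]
) -> tuple[pd.DataFrame, list[TraitProbe]]:
    """Per-sample flagging table over a panel (all thresholds must be set)."""
    table, not_assayed = extract_trait_betas(matrix, panel)
    probe_map = {p.probe_id: p for p in panel}
    if not table.empty:
        table["status"] = [
            flag_trait_status(row.beta, probe_map[row.probe_id])
            for row in table.itertuples()
        ]
    else:
        table["status"] = pd.Series(dtype=object)
    return table, not_assayed


def read_panel(path: str | Path) -> list[TraitProbe]:
    """Read a panel TSV with columns probe_id, trait, direction, threshold."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probe_id", "trait", "direction", "threshold"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"panel file missing columns: {sorted(missing)}")
    panel = []
    for _, row in frame.iterrows():
        threshold = float(row["threshold"]) if row["threshold"].strip() else None
        panel.append(
            TraitProbe(
                probe_id=row["probe_id"].strip(),
                trait_label=row["trait"].strip(),
                direction=row["direction"].strip(),
                threshold=threshold,
            )
        )
    return panel
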