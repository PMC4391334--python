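"""In-silico MspI restriction-digest assays for genotype validation.

MspI recognizes CCGG and cuts after the first C (C^CGG). A CpG whose C is
polymorphic can be genotyped on genomic DNA when it forms the inner CG of a
CCGG tetramer: the C allele leaves the site cuttable, the D allele destroys
it. Only fragment lengths are modeled (no sticky ends); any other CCGG
sites in the amplicon are assumed invariant and cut on every allele.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

from .errors import AssayDesignError, SequenceError
from .io_methylation import ProbeAnnotation

logger = logging.getLogger(__name__)

MSPI_SITE = "CCGG"
# MspI cuts C^CGG: offset of the cut within the recognition site.
MSPI_CUT_OFFSET = 1

_VALID_SEQ = re.compile(r"^[ACGT]*$")

# PCR primers for the two loci validated by gel-based MspI digest.
VALIDATED_PRIMERS: dict[str, dict[str, str]] = {
    "cg10695549": {
        "forward": "GCTGTAATTATACATCCAGCTATGG",
        "reverse": "TTTTTGTTTCCCTTCTGAGC",
    },
    "cg21028319": {
        "forward": "TTGCAAACGATGAGAACTGAG",
        "reverse": "CGTTTACCAGCCCATGCTA",
    },
}


@dataclass(frozen=True)
class DigestAssay:
    """One amplicon's MspI digest model with a single genotype-dependent site.

    ``site_positions`` lists every CCGG start index in ``amplicon_sequence``;
    ``target_site_index`` selects the occurrence covering the assayed CpG.
    """

    probe_id: str
    amplicon_sequence: str
    site_positions: tuple[int, ...] = field(default=())
    target_site_index: int = 0

    def __post_init__(self) -> None:
        found = tuple(find_mspi_sites(self.amplicon_sequence))
        positions = self.site_positions or found
        if positions != found:
            raise AssayDesignError(
                f"{self.probe_id}: declared site positions {positions} do not "
                f"match the amplicon scan {found}"
            )
        object.__setattr__(self, "site_positions", positions)
        if not positions:
            raise AssayDesignError(
                f"{self.probe_id}: amplicon contains no {MSPI_SITE} site"
            )
        if not 0 <= self.target_site_index < len(positions):
            raise AssayDesignError(
                f"{self.probe_id}: target_site_index {self.target_site_index} "
                f"out of range for {len(positions)} sites"
            )

    @property
    def target_position(self) -> int:
        return self.site_positions[self.target_site_index]


def find_mspi_sites(sequence: str) -> list[int]:
    """All (possibly overlapping) CCGG start positions, ascending, 0-based."""
    if not _VALID_SEQ.match(sequence):
        bad = next(c for c in sequence if c not in "ACGT")
        raise SequenceError(f"non-ACGT character {bad!r} in sequence")
    return [m.start() for m in re.finditer(rf"(?={MSPI_SITE})", sequence)]


def cpg_is_mspi_assayable(annotation: ProbeAnnotation) -> bool:
    """True iff the assayed CpG is the inner CG of a CCGG tetramer.

    The CpG's C must be preceded by C and its G followed by G in the probe
    source sequence; offsets at the sequence edge cannot form the tetramer.
    """
    seq = annotation.source_sequence
    off = annotation.cpg_offset
    if off < 1 or off + 2 >= len(seq):
        logger.warning(
            "probe %s: CpG at offset %d is at the sequence edge; cannot form %s",
            annotation.probe_id,
            off,
            MSPI_SITE,
        )
        return False
    return seq[off - 1 : off + 3] == MSPI_SITE


def _fragments(length: int, cut_sites: Sequence[int]) -> list[int]:
    """Fragment lengths after cutting at the given CCGG start positions."""
    cuts = sorted(p + MSPI_CUT_OFFSET for p in cut_sites)
    bounds = [0] + cuts + [length]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def predict_digest(assay: DigestAssay, genotype: str) -> list[int]:
    """Expected fragment-length multiset for a genotype, sorted ascending.

    The C allele is cut at the target site, the D allele is not;
    constitutive (non-target) sites are cut on every allele. CC and DD give
    one allele's fragment set; CD gives the union of both patterns (both
    chromosome populations run on the same gel lane).
    """
    if genotype not in ("CC", "CD", "DD"):
        raise ValueError(f"genotype must be CC, CD or DD, got {genotype!r}")
    length = len(assay.amplicon_sequence)
    constitutive = [
        p for i, p in enumerate(assay.site_positions) if i != assay.target_site_index
    ]
    cut_allele = _fragments(length, constitutive + [assay.target_position])
    uncut_allele = _fragments(length, constitutive)
    if genotype == "CC":
        fragments = cut_allele
    elif genotype == "DD":
        fragments = uncut_allele
    else:
        fragments = sorted(set(cut_allele) | set(uncut_allele))
    return sorted(fragments)


def assayability_table(annotations: Sequence[ProbeAnnotation]):
    """(probe_id, assayable, site_position) rows for a set of probes.

    ``site_position`` is the 0-based CCGG start within the source sequence
    (the assayed CpG's offset minus one) when assayable, else None.
    """
    rows = []
    for ann in annotations:
        assayable = cpg_is_mspi_assayable(ann)
        rows.append(
            {
                "probe_id": ann.probe_id,
                "assayable": assayable,
                "site_position": ann.cpg_offset - 1 if assayable else None,
            }
        )
    return rows
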