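"""Core domain types shared across the pipeline.

Tabular entities (variants, segments, events) travel as pandas DataFrames with
the column schemas declared here; small structured values (configs, derived
cutoffs, score cards) are dataclasses.  All genomic intervals are 1-based and
inclusive at both ends, in files and in memory alike.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class EventType(str, enum.Enum):
    """Copy-number event classes called from segment tables."""

    GAIN = "GAIN"
    LOSS = "LOSS"
    CNLOH = "CNLOH"


class TopologyType(str, enum.Enum):
    """Lesion-tree patterns.

    TYPE1: LEGH (L) and carcinoma (G) share a common branch.
    TYPE2: normal gland (N) and L share a common branch.
    TYPE3: N and G share a common branch.
    """

    TYPE1 = "TYPE1"
    TYPE2 = "TYPE2"
    TYPE3 = "TYPE3"
    UNRESOLVED = "UNRESOLVED"


class GeneRole(str, enum.Enum):
    """Cancer-gene role annotation (Cancer Gene Census style)."""

    ONCOGENE = "ONCOGENE"
    TSG = "TSG"
    BOTH = "BOTH"
    UNKNOWN = "UNKNOWN"


#: functional-class vocabulary of the variant tables
FUNC_CLASSES = (
    "exonic_nonsyn",
    "exonic_syn",
    "stopgain",
    "frameshift",
    "nonframeshift",
    "splicing",
    "intronic",
    "intergenic",
    "UTR",
)

#: classes counted as exonic for burden statistics
EXONIC_CLASSES = frozenset(
    {"exonic_nonsyn", "exonic_syn", "stopgain", "frameshift", "nonframeshift"}
)

#: exonic, non-synonymous classes eligible for short-variant scoring points
QUALIFYING_CLASSES = frozenset(
    {"exonic_nonsyn", "stopgain", "frameshift", "nonframeshift"}
)

#: presumed loss-of-function classes (CN-LOH scoring arm)
LOF_CLASSES = frozenset({"stopgain", "frameshift", "splicing"})

#: sample roles within one case
SAMPLE_ROLES = ("Nm", "N", "L", "G")

#: required columns of the variant table dialect
VARIANT_COLUMNS = (
    "case_id",
    "sample_id",
    "role",
    "chrom",
    "pos",
    "ref",
    "alt",
    "depth",
    "alt_reads",
    "vaf",
    "gene",
    "func_class",
    "pop_af_eas",
    "phase",
)

#: optional variant columns understood by downstream stages
VARIANT_OPTIONAL_COLUMNS = ("mean_base_quality", "context")

#: required columns of the SEG-like segment table dialect
SEGMENT_COLUMNS = (
    "case_id",
    "sample_id",
    "chrom",
    "start",
    "end",
    "copy_ratio",
    "minor_allele_fraction",
    "n_probes",
)

#: columns of the BED-compatible event table
EVENT_COLUMNS = (
    "case_id",
    "sample_id",
    "chrom",
    "start",
    "end",
    "event_type",
    "affected_haplotype",
)


@dataclass(frozen=True)
class CnlohCutoff:
    """Minor-allele-fraction threshold below which a copy-neutral segment is
    called CN-LOH, together with its derivation provenance."""

    value: float
    n_normals: int
    per_sample_p10: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 0.5:
            raise ValueError(f"cutoff {self.value} outside [0, 0.5]")


@dataclass
class GeneScoreCard:
    """Per-gene point tally of the candidate-driver scoring system."""

    gene: str
    sv_points: int = 0
    cna_points: int = 0
    per_case_evidence: list[tuple[str, str]] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.sv_points + self.cna_points


def interval_overlap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Overlap length of two 1-based inclusive intervals (0 if disjoint)."""
    return max(0, min(end_a, end_b) - max(start_a, start_b) + 1)


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive interval."""
    return end - start + 1
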