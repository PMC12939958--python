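"""Somatic filtering: germline subtraction against the matched myometrium
sample, quality thresholds, exonic/non-exonic partitioning, burden rates.

The default thresholds (base quality 20, depth 10, VAF 0.05) are
conventional FFPE-WES floor values; every test exercises the rule rather
than the constant, and all of them are overridable in ``FilterConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import EXONIC_CLASSES, FUNC_CLASSES

__all__ = [
    "FilterConfig",
    "subtract_germline",
    "quality_filter",
    "classify_exonic",
    "mutation_rate",
    "is_canonical_chrom",
    "is_mito_chrom",
]

_CANONICAL = {str(i) for i in range(1, 23)} | {"X", "Y"}
_MITO = {"M", "MT"}


def _strip_chr(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def is_canonical_chrom(name: str) -> bool:
    """True for autosomes and sex chromosomes, with or without a chr prefix."""
    return _strip_chr(str(name)) in _CANONICAL


def is_mito_chrom(name: str) -> bool:
    return _strip_chr(str(name)).upper() in _MITO


@dataclass(frozen=True)
class FilterConfig:
    min_mean_base_quality: float = 20.0
    min_depth: int = 10
    min_vaf: float = 0.05
    drop_unplaced_and_mito: bool = True
    germline_match_keys: tuple[str, ...] = ("chrom", "pos", "ref", "alt")

    def __post_init__(self) -> None:
        if self.min_mean_base_quality < 0 or self.min_depth < 0 or self.min_vaf < 0:
            raise ValueError("filter thresholds must be non-negative")


def subtract_germline(
    lesion_variants: pd.DataFrame,
    reference_variants: pd.DataFrame,
    keys: tuple[str, ...] = ("chrom", "pos", "ref", "alt"),
) -> pd.DataFrame:
    """Remove lesion variants whose site/allele key occurs in the matched
    normal-myometrium sample; the paired sample defines the germline set.

    Raises if the two tables carry different case identifiers, which would
    silently perform a cross-patient subtraction.
    """
    lesion_cases = set(lesion_variants["case_id"].unique())
    ref_cases = set(reference_variants["case_id"].unique())
    if lesion_cases and ref_cases and lesion_cases != ref_cases:
        raise ValueError(
            f"case mismatch between lesion ({sorted(lesion_cases)}) and "
            f"reference ({sorted(ref_cases)}) variants"
        )
    if lesion_variants.empty or reference_variants.empty:
        return lesion_variants.copy()
    ref_keys = set(map(tuple, reference_variants[list(keys)].itertuples(index=False)))
    mask = [
        tuple(row) not in ref_keys
        for row in lesion_variants[list(keys)].itertuples(index=False)
    ]
    return lesion_variants.loc[mask].copy()


def quality_filter(variants: pd.DataFrame, config: FilterConfig | None = None) -> pd.DataFrame:
    """Apply per-record quality predicates, preserving input order.

    Records lacking a ``mean_base_quality`` value pass that criterion.  With
    ``drop_unplaced_and_mito`` set, records on mitochondrial or unplaced
    contigs (anything outside the canonical autosome/sex-chromosome set) are
    removed.
    """
    config = config or FilterConfig()
    if variants.empty:
        return variants.copy()
    keep = (variants["depth"] >= config.min_depth) & (variants["vaf"] >= config.min_vaf)
    if "mean_base_quality" in variants.columns:
        bq = pd.to_numeric(variants["mean_base_quality"], errors="coerce")
        keep &= bq.isna() | (bq >= config.min_mean_base_quality)
    if config.drop_unplaced_and_mito:
        keep &= variants["chrom"].map(is_canonical_chrom)
    return variants.loc[keep].copy()


def classify_exonic(variants: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into (exonic, non_exonic) by functional class.

    Splicing, intronic, intergenic and UTR records are non-exonic; the
    partition is exhaustive and an unknown class raises.
    """
    unknown = set(variants["func_class"].unique()) - set(FUNC_CLASSES)
    if unknown:
        raise ValueError(f"unknown functional class value(s): {sorted(unknown)}")
    mask = variants["func_class"].isin(EXONIC_CLASSES)
    return variants.loc[mask].copy(), variants.loc[~mask].copy()


def mutation_rate(variants: pd.DataFrame, target_size_mb: float) -> float:
    """Mutations per megabase over a sequencing target of the given size."""
    if target_size_mb <= 0:
        raise ValueError("target size must be positive")
    return len(variants) / target_size_mb
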