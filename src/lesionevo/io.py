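"""Readers and writers for the pipeline's tab-separated dialects.

All interval columns are 1-based inclusive, in files and in memory.  Missing
values are written as ``NA``.  Readers validate required columns and basic
value constraints and report the first offending file line (header = line 1)
to make malformed inputs easy to locate; ``strict=False`` downgrades value
errors to row drops.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .records import EVENT_COLUMNS, SEGMENT_COLUMNS, VARIANT_COLUMNS

__all__ = [
    "read_variants",
    "write_variants",
    "read_segments",
    "write_segments",
    "read_events",
    "write_events",
    "read_gene_table",
    "packaged_gene_table_path",
    "load_cgc_roles",
    "read_gmt",
    "write_newick",
]

_NA = "NA"


def _read_tsv(path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", na_values=[_NA], keep_default_na=True)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV ({exc})") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return df


def _check(df: pd.DataFrame, mask: pd.Series, message: str, path, strict: bool) -> pd.DataFrame:
    bad = ~mask.fillna(False) if mask.isna().any() else ~mask
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        if strict:
            raise ValueError(f"{path}: line {line}: {message}")
        return df.loc[~bad]
    return df


def read_variants(path, strict: bool = True) -> pd.DataFrame:
    df = _read_tsv(path, VARIANT_COLUMNS)
    df = _check(df, df["pos"] >= 1, "pos must be >= 1", path, strict)
    df = _check(df, df["alt_reads"] <= df["depth"], "alt_reads exceeds depth", path, strict)
    df = _check(df, (df["vaf"] >= 0) & (df["vaf"] <= 1), "vaf outside [0, 1]", path, strict)
    df["phase"] = pd.to_numeric(df["phase"], errors="coerce").astype("Int64")
    return df.reset_index(drop=True)


def write_variants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.6g")


def read_segments(path, strict: bool = True) -> pd.DataFrame:
    df = _read_tsv(path, SEGMENT_COLUMNS)
    df = _check(df, df["start"] <= df["end"], "start exceeds end", path, strict)
    df = _check(df, df["copy_ratio"] >= 0, "negative copy ratio", path, strict)
    df = _check(
        df,
        (df["minor_allele_fraction"] >= 0) & (df["minor_allele_fraction"] <= 0.5),
        "minor allele fraction outside [0, 0.5]",
        path,
        strict,
    )
    return df.reset_index(drop=True)


def write_segments(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=_NA, float_format="%.6g")


def read_events(path, strict: bool = True) -> pd.DataFrame:
    df = _read_tsv(path, EVENT_COLUMNS)
    df = _check(df, df["start"] <= df["end"], "start exceeds end", path, strict)
    df["affected_haplotype"] = pd.to_numeric(
        df["affected_haplotype"], errors="coerce"
    ).astype("Int64")
    return df.reset_index(drop=True)


def write_events(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)


def packaged_gene_table_path():
    """Packaged synthetic gene-interval/role table on the artificial genome."""
    return resources.files("lesionevo.data") / "gene_table_synthetic.tsv"


def read_gene_table(path=None) -> pd.DataFrame:
    """Gene table TSV with columns gene, chrom, start, end, role."""
    if path is None:
        path = packaged_gene_table_path()
    df = _read_tsv(path, ("gene", "chrom", "start", "end", "role"))
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"{path}: duplicated gene {dup!r}")
    return df


def load_cgc_roles(path) -> pd.DataFrame:
    """Parse a Cancer Gene Census CSV export into a gene/role table.

    Uses the "Gene Symbol" and "Role in Cancer" columns; role strings
    containing both "oncogene" and "TSG" map to BOTH, either alone to the
    respective role, anything else to UNKNOWN.
    """
    df = pd.read_csv(path)
    if "Gene Symbol" not in df.columns or "Role in Cancer" not in df.columns:
        raise ValueError(f"{path}: not a CGC export (expected 'Gene Symbol'/'Role in Cancer')")

    def role_of(text) -> str:
        text = "" if pd.isna(text) else str(text).lower()
        onc, tsg = "oncogene" in text, "tsg" in text
        if onc and tsg:
            return "BOTH"
        if onc:
            return "ONCOGENE"
        if tsg:
            return "TSG"
        return "UNKNOWN"

    return pd.DataFrame(
        {"gene": df["Gene Symbol"].astype(str), "role": df["Role in Cancer"].map(role_of)}
    )


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 GMT fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))
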