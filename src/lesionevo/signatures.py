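"""96-context substitution spectra and supervised signature refitting.

Spectra follow the conventional COSMIC layout: six pyrimidine-strand
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G) crossed with the sixteen
5'/3' flanking-base combinations in alphabetical order, giving classes like
``A[C>A]A`` ... ``T[T>G]T``.  Refitting solves a non-negative least-squares
problem against a reference signature matrix; exposures normalized to one are
the reported signature proportions.  A small synthetic reference (SBS1-,
SBS2-, SBS5-, SBS13-like profiles plus a flat background) ships with the
package; a full COSMIC matrix in the same TSV layout can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "CONTEXTS_96",
    "Spectrum96",
    "SignatureExposure",
    "build_spectrum",
    "fit_exposures",
    "load_reference",
    "packaged_reference_path",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: the 96 trinucleotide-context substitution classes in conventional order
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

_CLASS_INDEX = {label: i for i, label in enumerate(CONTEXTS_96)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def class_of(ref: str, alt: str, context: str) -> int:
    """Index of the 96-class for one SNV given its trinucleotide context.

    ``context`` is the 3-mer centered on the variant on the reference strand;
    purine references are reverse-complemented onto the pyrimidine strand.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context) != 3 or any(b not in _BASES for b in context):
        raise ValueError(f"bad trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValueError(f"context {context!r} does not center on ref {ref!r}")
    if ref in "AG":
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    try:
        return _CLASS_INDEX[label]
    except KeyError:  # e.g. ref == alt
        raise ValueError(f"unclassifiable substitution {label}") from None


@dataclass
class Spectrum96:
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError("spectrum must have 96 entries")
        if (self.counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass
class SignatureExposure:
    signatures: tuple[str, ...]
    exposures: np.ndarray
    proportions: np.ndarray
    residual: float
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.signatures, map(float, self.proportions)))


def build_spectrum(
    snvs: pd.DataFrame,
    context_provider: Callable[[str, int], str] | None = None,
) -> Spectrum96:
    """Tally SNVs into a 96-context spectrum.

    Contexts come from the variant table's ``context`` column unless a
    ``context_provider`` callable mapping (chrom, pos) to a 3-mer is given.
    Indels raise; every record must have a resolvable context.
    """
    counts = np.zeros(96, dtype=int)
    if snvs.empty:
        return Spectrum96(counts)
    has_col = "context" in snvs.columns
    if context_provider is None and not has_col:
        raise ValueError("no context column and no context_provider given")
    for row in snvs.itertuples(index=False):
        if context_provider is not None:
            ctx = context_provider(row.chrom, int(row.pos))
        else:
            ctx = row.context
        if not isinstance(ctx, str):
            raise ValueError(f"missing context at {row.chrom}:{row.pos}")
        counts[class_of(row.ref, row.alt, ctx)] += 1
    return Spectrum96(counts)


def fit_exposures(spectrum: Spectrum96 | np.ndarray, reference: pd.DataFrame) -> SignatureExposure:
    """Refit a spectrum against reference signatures by non-negative least
    squares: minimize ||spectrum - R e||_2 subject to e >= 0.

    ``reference`` is a 96 x K DataFrame (rows indexed by context label,
    columns named by signature) whose columns each sum to 1.  An all-zero
    spectrum yields zero exposures flagged degenerate.
    """
    counts = spectrum.counts if isinstance(spectrum, Spectrum96) else np.asarray(spectrum, float)
    if reference.shape[0] != 96 or reference.shape[1] == 0:
        raise ValueError("reference must be 96 rows by >= 1 signature column")
    colsums = reference.sum(axis=0).to_numpy()
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("reference signature columns must each sum to 1")
    names = tuple(reference.columns)
    if counts.sum() == 0:
        zeros = np.zeros(len(names))
        return SignatureExposure(names, zeros, np.full(len(names), np.nan), 0.0, degenerate=True)
    exposures, residual = nnls(reference.to_numpy(), counts.astype(float))
    total = exposures.sum()
    proportions = exposures / total if total > 0 else np.full(len(names), np.nan)
    return SignatureExposure(names, exposures, proportions, float(residual), degenerate=total == 0)


def load_reference(path=None) -> pd.DataFrame:
    """Load a signature matrix TSV (context label column + one column per
    signature), reordered to the conventional 96-class layout."""
    if path is None:
        path = packaged_reference_path()
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    missing = set(CONTEXTS_96) - set(df.index)
    if missing:
        raise ValueError(f"reference matrix lacks {len(missing)} context rows")
    return df.loc[list(CONTEXTS_96)]


def packaged_reference_path():
    """Path to the packaged synthetic mini-reference signature matrix."""
    return resources.files("lesionevo.data") / "sbs_reference_synthetic.tsv"


def mixture_profile(weights: Mapping[str, float], reference: pd.DataFrame | None = None) -> np.ndarray:
    """Probability vector over 96 classes for a named signature mixture."""
    if reference is None:
        reference = load_reference()
    p = np.zeros(96)
    for name, w in weights.items():
        p += w * reference[name].to_numpy()
    s = p.sum()
    if s <= 0:
        raise ValueError("mixture weights sum to zero")
    return p / s
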