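"""Copy-number event calling from segment tables.

Gains and losses are thresholded on the tumor/normal copy ratio (defaults
>1.1 and <0.9, sensitive to events clonal in at least ~20% of cells).
Copy-neutral LOH (CN-LOH) is a segment with no total copy-number change
(ratio inside the closed neutral band) whose minor allele fraction falls
below a cutoff derived from normal samples: the mean minus three sample
standard deviations of the per-normal-sample 10th percentiles of minor
allele fraction.  Haplotype assignment reads phased heterozygous variants
inside each event: the haplotype whose alleles systematically sit below 50%
VAF is the lost one (for gains, above 50% is the gained one).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .records import EVENT_COLUMNS, CnlohCutoff, EventType, interval_overlap

__all__ = [
    "derive_cnloh_cutoff",
    "call_events",
    "assign_haplotype",
    "assign_haplotypes",
    "mutual_events",
]

GAIN_CUTOFF_DEFAULT = 1.1
LOSS_CUTOFF_DEFAULT = 0.9


def derive_cnloh_cutoff(
    normal_mafs: Mapping[str, Sequence[float]] | pd.DataFrame,
    percentile: float = 10.0,
) -> CnlohCutoff:
    """Derive the CN-LOH minor-allele-fraction cutoff from normal samples.

    For each normal sample, the 10th percentile (linear interpolation between
    order statistics) of its minor-allele-fraction values is computed; the
    cutoff is ``mean(p10) - 3 * SD(p10)`` across samples, with the sample
    standard deviation (n-1 denominator), clamped to [0, 0.5].  At least two
    normal samples are required for the SD to exist.
    """
    if isinstance(normal_mafs, pd.DataFrame):
        normal_mafs = {
            str(sid): grp["minor_allele_fraction"].to_numpy()
            for sid, grp in normal_mafs.groupby("sample_id", sort=True)
        }
    if len(normal_mafs) < 2:
        raise ValueError("need >= 2 normal samples to derive the cutoff")
    p10 = []
    for sid, values in normal_mafs.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError(f"normal sample {sid!r} has no MAF values")
        p10.append(float(np.percentile(values, percentile)))
    p10_arr = np.asarray(p10)
    value = float(p10_arr.mean() - 3.0 * p10_arr.std(ddof=1))
    value = float(np.clip(value, 0.0, 0.5))
    return CnlohCutoff(value=value, n_normals=len(p10), per_sample_p10=tuple(p10))


def _classify_segment(
    ratio: float, maf: float, gain_cutoff: float, loss_cutoff: float, cnloh_value: float
) -> str | None:
    if ratio > gain_cutoff:
        return EventType.GAIN.value
    if ratio < loss_cutoff:
        return EventType.LOSS.value
    if maf < cnloh_value:
        return EventType.CNLOH.value
    return None


def call_events(
    segments: pd.DataFrame,
    gain_cutoff: float = GAIN_CUTOFF_DEFAULT,
    loss_cutoff: float = LOSS_CUTOFF_DEFAULT,
    cnloh_cutoff: CnlohCutoff | float = 0.44,
) -> pd.DataFrame:
    """Call GAIN / LOSS / CN-LOH events segment-wise and merge adjacent
    same-type calls on each chromosome into single events.

    Segments with copy ratio above ``gain_cutoff`` are gains, below
    ``loss_cutoff`` losses; segments inside the closed neutral band whose
    minor allele fraction falls below the CN-LOH cutoff are CN-LOH; all other
    segments yield no event.
    """
    if not loss_cutoff < 1.0 < gain_cutoff:
        raise ValueError("cutoffs must satisfy loss < 1 < gain")
    cnloh_value = cnloh_cutoff.value if isinstance(cnloh_cutoff, CnlohCutoff) else float(cnloh_cutoff)
    if (segments["start"] > segments["end"]).any():
        bad = segments.loc[segments["start"] > segments["end"]].index[0]
        raise ValueError(f"malformed segment (start > end) at row {bad}")

    events: list[dict] = []
    for (case_id, sample_id, chrom), grp in segments.groupby(
        ["case_id", "sample_id", "chrom"], sort=True
    ):
        grp = grp.sort_values("start")
        current: dict | None = None
        for row in grp.itertuples(index=False):
            etype = _classify_segment(
                row.copy_ratio, row.minor_allele_fraction, gain_cutoff, loss_cutoff, cnloh_value
            )
            if etype is None:
                if current is not None:
                    events.append(current)
                    current = None
                continue
            if (
                current is not None
                and current["event_type"] == etype
                and row.start <= current["end"] + 1
            ):
                current["end"] = max(current["end"], row.end)
            else:
                if current is not None:
                    events.append(current)
                current = {
                    "case_id": case_id,
                    "sample_id": sample_id,
                    "chrom": chrom,
                    "start": int(row.start),
                    "end": int(row.end),
                    "event_type": etype,
                    "affected_haplotype": pd.NA,
                }
        if current is not None:
            events.append(current)
    out = pd.DataFrame(events, columns=list(EVENT_COLUMNS))
    out["affected_haplotype"] = out["affected_haplotype"].astype("Int64")
    return out


def assign_haplotype(event: Mapping, phased_variants: pd.DataFrame) -> object:
    """Majority-vote the affected haplotype of one event from phased
    heterozygous variants overlapping its interval.

    For LOSS and CN-LOH the affected haplotype is the lost one: a phase-h
    variant with VAF below 0.5 votes that haplotype h was lost.  For GAIN the
    affected haplotype is the gained one: VAF above 0.5 on phase h votes h.
    Ties or absence of informative variants give ``pd.NA`` (unknown).
    """
    if phased_variants.empty:
        return pd.NA
    v = phased_variants
    mask = (
        (v["sample_id"] == event["sample_id"])
        & (v["chrom"] == event["chrom"])
        & (v["pos"] >= event["start"])
        & (v["pos"] <= event["end"])
        & v["phase"].isin([0, 1])
    )
    v = v.loc[mask]
    if v.empty:
        return pd.NA
    votes = np.zeros(2)
    gain = event["event_type"] == EventType.GAIN.value
    for row in v.itertuples(index=False):
        if row.vaf == 0.5:
            continue
        high = row.vaf > 0.5
        phase = int(row.phase)
        if gain:
            votes[phase if high else 1 - phase] += 1
        else:
            votes[1 - phase if high else phase] += 1
    if votes[0] == votes[1]:
        return pd.NA
    return int(np.argmax(votes))


def assign_haplotypes(events: pd.DataFrame, phased_variants: pd.DataFrame) -> pd.DataFrame:
    """Vectorized convenience wrapper: assign_haplotype over an event table."""
    out = events.copy()
    assigned = [
        assign_haplotype(row._asdict(), phased_variants)
        for row in events.itertuples(index=False)
    ]
    out["affected_haplotype"] = pd.array(assigned, dtype="Int64")
    return out


def mutual_events(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    min_reciprocal_overlap: float = 0.5,
) -> pd.DataFrame:
    """Pair events of the same type from two samples of one case whose
    intervals reciprocally overlap by at least the given fraction."""
    cases = set(events_a["case_id"]) | set(events_b["case_id"])
    if len(cases) > 1:
        raise ValueError(f"events from multiple cases: {sorted(cases)}")
    pairs = []
    for ea in events_a.itertuples(index=False):
        for eb in events_b.itertuples(index=False):
            if ea.event_type != eb.event_type or ea.chrom != eb.chrom:
                continue
            ov = interval_overlap(ea.start, ea.end, eb.start, eb.end)
            len_a = ea.end - ea.start + 1
            len_b = eb.end - eb.start + 1
            if ov / len_a >= min_reciprocal_overlap and ov / len_b >= min_reciprocal_overlap:
                pairs.append(
                    {
                        "case_id": ea.case_id,
                        "chrom": ea.chrom,
                        "event_type": ea.event_type,
                        "sample_a": ea.sample_id,
                        "start_a": ea.start,
                        "end_a": ea.end,
                        "sample_b": eb.sample_id,
                        "start_b": eb.start,
                        "end_b": eb.end,
                    }
                )
    return pd.DataFrame(
        pairs,
        columns=[
            "case_id",
            "chrom",
            "event_type",
            "sample_a",
            "start_a",
            "end_a",
            "sample_b",
            "start_b",
            "end_b",
        ],
    )
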