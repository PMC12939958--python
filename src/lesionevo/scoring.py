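"""Candidate-driver gene scoring against a Cancer Gene Census-style role table.

The score of a gene sums two evidence streams over the cohort's carcinoma
(G-role) samples:

* short-variant points — one point per case carrying at least one rare
  (population allele frequency < 0.01 in the East Asian gnomAD slice, or
  unregistered) exonic non-synonymous variant in the gene, capped at one
  point per case regardless of how many such variants the case carries;
* CNA points — one point per case with a biologically plausible copy-number
  event over the gene: gain of an oncogene, loss of a tumor suppressor, or
  CN-LOH where a loss-of-function variant (stopgain/frameshift/splicing)
  lies on the retained haplotype.  CN-LOH with unresolved haplotype or
  without an interpretable variant is never scored.

Genes totalling at least the threshold (default 2) are candidates; the
threshold-sensitivity mode re-emits candidate sets at 2/3/4/5, which are
nested by construction.  Gene-set over-representation of the candidates is a
one-sided hypergeometric test with Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .records import LOF_CLASSES, QUALIFYING_CLASSES, EventType, GeneRole, interval_overlap
from .stats import bh_adjust

__all__ = [
    "qualify_short_variant",
    "score_short_variants",
    "qualify_cna",
    "score_cohort",
    "enrichment",
    "POP_AF_MAX",
    "SENSITIVITY_THRESHOLDS",
]

POP_AF_MAX = 0.01
SENSITIVITY_THRESHOLDS = (2, 3, 4, 5)


def qualify_short_variant(variant: Mapping) -> bool:
    """True for exonic, non-synonymous variants that are rare (< 0.01) or
    absent from the East Asian population frequency annotation."""
    if variant["func_class"] not in QUALIFYING_CLASSES:
        return False
    af = variant.get("pop_af_eas")
    return bool(af is None or pd.isna(af) or float(af) < POP_AF_MAX)


def score_short_variants(gas_variants: pd.DataFrame) -> dict[str, dict]:
    """Per-gene short-variant points over carcinoma samples.

    A gene earns one point per distinct case with at least one qualifying
    variant (a case never contributes more than one point to a gene).
    Returns {gene: {"points": int, "cases": sorted case ids}}.
    """
    per_gene: dict[str, set] = {}
    if len(gas_variants):
        for row in gas_variants.itertuples(index=False):
            d = row._asdict()
            gene = d.get("gene")
            if gene is None or pd.isna(gene):
                continue
            if qualify_short_variant(d):
                per_gene.setdefault(str(gene), set()).add(d["case_id"])
    return {
        g: {"points": len(cases), "cases": sorted(cases)} for g, cases in per_gene.items()
    }


def _retained_haplotype(affected) -> int | None:
    if affected is None or pd.isna(affected):
        return None
    return 1 - int(affected)


def qualify_cna(
    gene_interval: Mapping,
    role: str | GeneRole,
    events: pd.DataFrame,
    gene_variants: pd.DataFrame,
    require_containment: bool = False,
) -> bool:
    """Does one case's carcinoma sample carry a biologically plausible
    copy-number event over the gene?

    ``events`` are that case's called events (any sample filtering done by
    the caller); ``gene_variants`` that case's carcinoma variants in the
    gene, used only by the CN-LOH arm.  Unknown-role genes can only score
    through the CN-LOH-with-LoF arm.
    """
    role = GeneRole(role)
    gs, ge, gchrom = gene_interval["start"], gene_interval["end"], gene_interval["chrom"]
    for ev in events.itertuples(index=False):
        if ev.chrom != gchrom:
            continue
        ov = interval_overlap(gs, ge, ev.start, ev.end)
        contained = ev.start <= gs and ev.end >= ge
        if (require_containment and not contained) or ov == 0:
            continue
        if ev.event_type == EventType.GAIN.value and role in (GeneRole.ONCOGENE, GeneRole.BOTH):
            return True
        if ev.event_type == EventType.LOSS.value and role in (GeneRole.TSG, GeneRole.BOTH):
            return True
        if ev.event_type == EventType.CNLOH.value:
            retained = _retained_haplotype(ev.affected_haplotype)
            if retained is None or gene_variants.empty:
                continue
            lof = gene_variants[
                gene_variants["func_class"].isin(LOF_CLASSES)
                & (pd.to_numeric(gene_variants["phase"], errors="coerce") == retained)
            ]
            if len(lof):
                return True
    return False


def score_cohort(
    gas_variants: pd.DataFrame,
    gas_events: pd.DataFrame,
    gene_table: pd.DataFrame,
    threshold: int = 2,
    require_containment: bool = False,
) -> dict:
    """Full cohort scoring over carcinoma samples.

    ``gene_table`` needs columns gene, chrom, start, end, role.  Returns a
    dict with the ranked score table (total descending, ties alphabetical),
    the candidate list at ``threshold`` and the nested sensitivity sets at
    thresholds 2/3/4/5.
    """
    sv = score_short_variants(gas_variants)
    rows = []
    gene_index = {r.gene: r for r in gene_table.itertuples(index=False)}
    cases = sorted(set(gas_variants["case_id"]) | set(gas_events["case_id"]))
    for gene, info in sorted(gene_index.items()):
        sv_points = sv.get(gene, {}).get("points", 0)
        evidence = [(c, "SV") for c in sv.get(gene, {}).get("cases", [])]
        cna_points = 0
        for case in cases:
            ev_case = gas_events[gas_events["case_id"] == case]
            if ev_case.empty:
                continue
            var_case = gas_variants[
                (gas_variants["case_id"] == case) & (gas_variants["gene"] == gene)
            ]
            if qualify_cna(
                {"chrom": info.chrom, "start": info.start, "end": info.end},
                info.role,
                ev_case,
                var_case,
                require_containment=require_containment,
            ):
                cna_points += 1
                evidence.append((case, "CNA"))
        if sv_points or cna_points:
            rows.append(
                {
                    "gene": gene,
                    "sv_points": sv_points,
                    "cna_points": cna_points,
                    "total": sv_points + cna_points,
                    "evidence": ";".join(f"{c}:{k}" for c, k in sorted(evidence)),
                }
            )
    scores = pd.DataFrame(rows, columns=["gene", "sv_points", "cna_points", "total", "evidence"])
    if len(scores):
        scores = scores.sort_values(["total", "gene"], ascending=[False, True]).reset_index(
            drop=True
        )
    candidates = scores.loc[scores["total"] >= threshold, "gene"].tolist()
    sensitivity = {
        t: scores.loc[scores["total"] >= t, "gene"].tolist() for t in SENSITIVITY_THRESHOLDS
    }
    return {"scores": scores, "candidates": candidates, "sensitivity": sensitivity}


def enrichment(
    candidates: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of the candidate list in
    each gene set, BH-corrected across sets.

    With M = |universe|, K = |set ∩ universe|, n = |candidates| and k the
    candidate/set overlap, p = P(X >= k) for X ~ Hypergeom(M, K, n).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    cand = set(candidates)
    if not cand <= universe_set:
        raise ValueError("candidates must be a subset of the universe")
    rows = []
    for name, members in gene_sets.items():
        in_univ = set(members) & universe_set
        k = len(cand & in_univ)
        p = float(hypergeom.sf(k - 1, len(universe_set), len(in_univ), len(cand)))
        rows.append({"set": name, "overlap": k, "set_size": len(in_univ), "p_value": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p_value"])
    if len(out):
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["q_value"] < q_threshold
    else:
        out["q_value"] = []
        out["significant"] = []
    return out
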