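"""End-to-end pipeline driver: filter -> CNA -> signatures -> phylogeny ->
scoring -> cohort statistics, with per-stage TSV outputs and a deterministic
JSON summary.

The CN-LOH cutoff is derived from the normal-myometrium (Nm) segments of the
input cohort and logged alongside every other threshold actually applied.
Haplotype assignment deliberately uses the *unfiltered* per-sample variant
tables: the phased heterozygous sites informing allele-specific copy number
are germline and would otherwise have been removed by germline subtraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna, filtering, io, phylogeny, scoring, signatures, stats
from .records import CnlohCutoff
from .synthetic_data import SimConfig, write_cohort

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("lesionevo")


@dataclass
class PipelineConfig:
    variants_path: str | None = None
    segments_path: str | None = None
    out_dir: str = "lesionevo_out"
    gene_table_path: str | None = None
    signature_reference_path: str | None = None
    gene_sets_path: str | None = None
    # filtering
    min_mean_base_quality: float = 20.0
    min_depth: int = 10
    min_vaf: float = 0.05
    drop_unplaced_and_mito: bool = True
    # CNA calling
    gain_cutoff: float = 1.1
    loss_cutoff: float = 0.9
    cnloh_cutoff: float | None = None  # derived from Nm segments when None
    min_reciprocal_overlap: float = 0.5
    # scoring
    scoring_threshold: int = 2
    # misc
    seed: int = 0
    log_level: str = "INFO"
    sim: dict = field(default_factory=dict)  # SimConfig overrides when simulating


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


@_stage("filter")
def _filter_stage(variants: pd.DataFrame, fconf: filtering.FilterConfig) -> pd.DataFrame:
    somatic_parts = []
    for case_id, case_vars in variants.groupby("case_id", sort=True):
        nm = case_vars[case_vars["role"] == "Nm"]
        lesions = case_vars[case_vars["role"] != "Nm"]
        subtracted = filtering.subtract_germline(lesions, nm, keys=fconf.germline_match_keys)
        somatic_parts.append(filtering.quality_filter(subtracted, fconf))
    somatic = pd.concat(somatic_parts, ignore_index=True) if somatic_parts else variants.iloc[0:0]
    log.info("somatic variants after filtering: %d", len(somatic))
    return somatic


@_stage("cna")
def _cna_stage(segments: pd.DataFrame, variants: pd.DataFrame, config: PipelineConfig):
    nm_segments = segments[segments["sample_id"].str.endswith("_Nm")]
    if config.cnloh_cutoff is not None:
        cutoff = CnlohCutoff(value=config.cnloh_cutoff, n_normals=0)
    else:
        cutoff = cna.derive_cnloh_cutoff(nm_segments)
    log.info("CN-LOH minor-allele-fraction cutoff: %.4f (from %d normals)", cutoff.value, cutoff.n_normals)
    lesion_segments = segments[~segments["sample_id"].str.endswith("_Nm")]
    events = cna.call_events(
        lesion_segments,
        gain_cutoff=config.gain_cutoff,
        loss_cutoff=config.loss_cutoff,
        cnloh_cutoff=cutoff,
    )
    phased = variants[variants["phase"].notna()]
    events = cna.assign_haplotypes(events, phased)
    mutual_parts = []
    for case_id, case_events in events.groupby("case_id", sort=True):
        ev_l = case_events[case_events["sample_id"].str.endswith("_L")]
        ev_g = case_events[case_events["sample_id"].str.endswith("_G")]
        if len(ev_l) and len(ev_g):
            mutual_parts.append(
                cna.mutual_events(ev_l, ev_g, min_reciprocal_overlap=config.min_reciprocal_overlap)
            )
    mutual = (
        pd.concat(mutual_parts, ignore_index=True)
        if mutual_parts
        else pd.DataFrame(columns=["case_id", "chrom", "event_type", "sample_a", "start_a", "end_a", "sample_b", "start_b", "end_b"])
    )
    return cutoff, events, mutual


@_stage("signatures")
def _signature_stage(somatic: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    rows = []
    snvs = somatic[(somatic["ref"].str.len() == 1) & (somatic["alt"].str.len() == 1)]
    for sample_id, sample_snvs in snvs.groupby("sample_id", sort=True):
        spectrum = signatures.build_spectrum(sample_snvs)
        exposure = signatures.fit_exposures(spectrum, reference)
        row = {"sample_id": sample_id, "n_snvs": int(spectrum.total), "residual": exposure.residual}
        row.update({f"prop_{k}": v for k, v in exposure.as_dict().items()})
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("phylogeny")
def _phylogeny_stage(somatic: pd.DataFrame, events: pd.DataFrame, out_dir: Path):
    per_case = {}
    trees_dir = out_dir / "trees"
    trees_dir.mkdir(parents=True, exist_ok=True)
    for case_id, case_vars in somatic.groupby("case_id", sort=True):
        by_role = {
            role: grp for role, grp in case_vars.groupby("role", sort=True)
        }
        ordered = {r: by_role[r] for r in ("N", "L", "G") if r in by_role}
        if len(ordered) < 2:
            per_case[case_id] = {"topology_type": "UNRESOLVED", "parsimony_score": 0}
            continue
        matrix = phylogeny.build_matrix(ordered)
        tree = phylogeny.parsimony_tree(matrix)
        topo = phylogeny.classify_topology(tree).value
        case_events = events[events["case_id"] == case_id]
        ev_by_role = {}
        for role in ("N", "L", "G"):
            sub = case_events[case_events["sample_id"].str.endswith(f"_{role}")]
            if role in ordered:
                ev_by_role[role] = sub
        cna_tree = phylogeny.cna_event_tree(ev_by_role)
        cna_topo = phylogeny.classify_topology(cna_tree).value
        if tree.newick:
            io.write_newick(tree.newick, trees_dir / f"{case_id}_variants.nwk")
        if cna_tree.newick:
            io.write_newick(cna_tree.newick, trees_dir / f"{case_id}_cna.nwk")
        per_case[case_id] = {
            "topology_type": topo,
            "parsimony_score": tree.score,
            "cna_topology_type": cna_topo,
            "trees_concordant": bool(topo == cna_topo and topo != "UNRESOLVED"),
        }
    return per_case


def _shared_vaf_stage(somatic: pd.DataFrame) -> dict | None:
    vaf_l, vaf_g = [], []
    for case_id, case_vars in somatic.groupby("case_id", sort=True):
        key_cols = ["chrom", "pos", "ref", "alt"]
        lv = case_vars[case_vars["role"] == "L"]
        gv = case_vars[case_vars["role"] == "G"]
        if lv.empty or gv.empty:
            continue
        merged = lv.merge(gv, on=key_cols, suffixes=("_L", "_G"))
        vaf_l.extend(merged["vaf_L"].tolist())
        vaf_g.extend(merged["vaf_G"].tolist())
    if not vaf_l:
        return None
    cmp = phylogeny.shared_vaf_comparison(vaf_l, vaf_g, labels=("L", "G"))
    return {
        "n_shared": len(vaf_l),
        "mean_vaf_L": cmp["mean_L"],
        "mean_vaf_G": cmp["mean_G"],
        "mean_difference": cmp["mean_difference"],
        "p_value": cmp["p_value"],
    }


@_stage("score")
def _score_stage(somatic: pd.DataFrame, events: pd.DataFrame, gene_table: pd.DataFrame, threshold: int):
    gas_vars = somatic[somatic["role"] == "G"]
    gas_events = events[events["sample_id"].str.endswith("_G")]
    return scoring.score_cohort(gas_vars, gas_events, gene_table, threshold=threshold)


@_stage("stats")
def _stats_stage(somatic: pd.DataFrame) -> dict:
    burdens = {
        role: grp.groupby("sample_id").size().tolist()
        for role, grp in somatic.groupby("role", sort=True)
        if role in ("N", "L", "G")
    }
    groups = [burdens[r] for r in ("N", "L", "G") if r in burdens and burdens[r]]
    labels = [r for r in ("N", "L", "G") if r in burdens and burdens[r]]
    out = {"burden_per_sample": burdens}
    if len(groups) >= 2:
        pairwise = stats.corrected_pairwise(groups, labels=labels)
        out["kruskal_wallis"] = {
            "statistic": pairwise["omnibus"].statistic,
            "p_value": pairwise["omnibus"].p_value,
        }
        out["pairwise"] = [
            {"pair": list(p["pair"]), "p_value": p["result"].p_value, "p_adjusted": p["p_adjusted"]}
            for p in pairwise["pairwise"]
        ]
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; writes per-stage TSVs, Newick trees and a
    deterministic ``summary.json`` under ``config.out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.variants_path is None or config.segments_path is None:
        sim_conf = SimConfig(seed=config.seed, **config.sim)
        paths = write_cohort(sim_conf, out_dir / "sim")
        variants_path, segments_path = paths["variants"], paths["segments"]
        log.info("simulated cohort written under %s", out_dir / "sim")
    else:
        variants_path, segments_path = config.variants_path, config.segments_path

    variants = io.read_variants(variants_path)
    segments = io.read_segments(segments_path)
    gene_table = io.read_gene_table(config.gene_table_path)
    reference = signatures.load_reference(config.signature_reference_path)

    fconf = filtering.FilterConfig(
        min_mean_base_quality=config.min_mean_base_quality,
        min_depth=config.min_depth,
        min_vaf=config.min_vaf,
        drop_unplaced_and_mito=config.drop_unplaced_and_mito,
    )
    somatic = _filter_stage(variants, fconf)
    cutoff, events, mutual = _cna_stage(segments, variants, config)
    exposures = _signature_stage(somatic, reference)
    per_case = _phylogeny_stage(somatic, events, out_dir)
    shared_vaf = _shared_vaf_stage(somatic)
    score_result = _score_stage(somatic, events, gene_table, config.scoring_threshold)
    cohort_stats = _stats_stage(somatic)

    io.write_variants(somatic, out_dir / "somatic.tsv")
    io.write_events(events, out_dir / "events.tsv")
    mutual.to_csv(out_dir / "mutual_events.tsv", sep="\t", index=False, na_rep="NA")
    exposures.to_csv(out_dir / "exposures.tsv", sep="\t", index=False, na_rep="NA", float_format="%.6g")
    score_result["scores"].to_csv(out_dir / "scores.tsv", sep="\t", index=False, na_rep="NA")

    if config.gene_sets_path:
        gene_sets = io.read_gmt(config.gene_sets_path)
        enr = scoring.enrichment(
            score_result["candidates"], gene_sets, gene_table["gene"].tolist()
        )
        enr.to_csv(out_dir / "enrichment.tsv", sep="\t", index=False, na_rep="NA", float_format="%.6g")

    summary = {
        # config echo without filesystem paths: those may differ between
        # otherwise-identical runs and live in the log instead
        "config": {
            k: v
            for k, v in asdict(config).items()
            if not k.endswith(("_path", "_dir")) and (not isinstance(v, dict) or v)
        },
        "seed": config.seed,
        "cnloh_cutoff": {
            "value": cutoff.value,
            "n_normals": cutoff.n_normals,
            "per_sample_p10": list(cutoff.per_sample_p10),
        },
        "thresholds": {
            "gain_cutoff": config.gain_cutoff,
            "loss_cutoff": config.loss_cutoff,
            "min_depth": config.min_depth,
            "min_vaf": config.min_vaf,
            "min_mean_base_quality": config.min_mean_base_quality,
            "scoring_threshold": config.scoring_threshold,
        },
        "n_somatic_variants": int(len(somatic)),
        "n_cna_events": int(len(events)),
        "n_mutual_cna_events": int(len(mutual)),
        "signature_proportions": {
            row["sample_id"]: {
                k.removeprefix("prop_"): row[k] for k in exposures.columns if k.startswith("prop_")
            }
            for _, row in exposures.iterrows()
        },
        "cases": per_case,
        "shared_vaf": shared_vaf,
        "candidate_genes": score_result["candidates"],
        "sensitivity": {str(k): v for k, v in score_result["sensitivity"].items()},
        "statistics": cohort_stats,
    }
    summary = _round_floats(summary)
    (out_dir / "summary.json").write_text(json.dumps(summary, sort_keys=True, indent=2) + "\n")
    log.info("summary written to %s", out_dir / "summary.json")
    return summary
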