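"""Clonal-evolution cohort simulator with a full truth ledger.

Each simulated case emits four matched samples on an artificial diploid
genome (default 22 chromosomes x 10 Mb): normal myometrium (Nm, the germline
reference), normal cervical gland (N), precursor lesion (L, LEGH-like) and
carcinoma (G, GAS-like).  Somatic variants are organized into a trunk shared
by all lesions, a topology-defining shared branch (Type 1: L+G, Type 2: N+L,
Type 3: N+G) and per-lesion private branches; read counts are binomial at a
Poisson depth, so variant allele fractions carry realistic sampling noise.
Carcinoma copies of variants carried by both L and G receive an additive
expected-VAF shift (default +0.06, emulating the higher clonality observed
in carcinoma).  Copy-number events (gain, loss, copy-neutral LOH) are
planted with a known affected haplotype and phased heterozygous germline
variants inside each event so haplotype assignment is recoverable; segment
copy ratios get Gaussian noise and neutral minor allele fractions sit just
below 0.5.  Substitution contexts follow an SBS1-dominant mixture (default
weight 0.7 on the clock-like C>T-at-CpG profile, flat background otherwise).

Candidate-driver recovery is well-posed by construction: planted driver
genes carry qualifying exonic variants in at least two cases (some with a
plausible CNA or a CN-LOH plus phased loss-of-function variant), planted
passenger genes in at most one case, and background somatic variants never
receive qualifying functional classes nor do background copy-number events
overlap gene intervals (they fall in the gene-free tail of each chromosome).
Every emitted variant and segment is labeled in the truth ledger, and a
fixed seed reproduces the output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import read_gene_table, write_segments, write_variants
from .records import TopologyType
from .signatures import CONTEXTS_96, load_reference, revcomp

__all__ = [
    "SimConfig",
    "CaseBundle",
    "TruthLedger",
    "simulate_case",
    "simulate_cohort",
    "simulate_spectrum",
    "write_cohort",
]

DEFAULT_TOPOLOGIES = ("TYPE1", "TYPE2", "TYPE1", "TYPE1", "TYPE1", "TYPE3", "TYPE2")

#: lesion pair sharing the topology-defining branch
BRANCH_OF_TYPE = {"TYPE1": ("L", "G"), "TYPE2": ("N", "L"), "TYPE3": ("N", "G")}

#: expected VAF of phased germline hets inside an event, by event type,
#: keyed (affected haplotype carrier, other haplotype carrier)
_EVENT_HET_VAF = {"CNLOH": None, "LOSS": (0.35, 0.65), "GAIN": (0.6, 0.4)}

_GENE_REGION_END = 6_000_000  # genes live below this; background CNAs above


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the simulator.

    Counts are per case (variants) or per lesion sample (CNA events);
    fractions live in [0, 1].  ``seed`` fixes the full output byte for byte.
    """

    n_cases: int = 7
    topology_types: tuple[str, ...] | str = DEFAULT_TOPOLOGIES
    n_germline_variants: int = 120
    n_trunk_variants: int = 40
    n_shared_variants: int = 50
    n_private_variants: int = 10
    mean_depth: float = 100.0
    purity: float = 0.4
    vaf_shift: float = 0.06
    n_cna_events: Mapping[str, int] = field(
        default_factory=lambda: {"N": 0, "L": 1, "G": 4}
    )
    n_shared_cna_events: int = 1
    cnloh_maf: float = 0.30
    sbs1_weight: float = 0.7
    copy_ratio_sigma: float = 0.03
    maf_sigma: float = 0.02
    phase_switch_rate: float = 0.0
    n_planted_drivers: int = 5
    n_passenger_genes: int = 200
    n_phased_hets_per_event: int = 8
    cases_without_normal_gland: tuple[int, ...] = ()
    chrom_count: int = 22
    chrom_length: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_cases,
            self.n_germline_variants,
            self.n_trunk_variants,
            self.n_shared_variants,
            self.n_private_variants,
            self.n_shared_cna_events,
            self.n_planted_drivers,
            self.n_passenger_genes,
            self.n_phased_hets_per_event,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be non-negative")
        if any(v < 0 for v in self.n_cna_events.values()):
            raise ValueError("per-lesion CNA counts must be non-negative")
        fractions = (
            self.purity,
            self.vaf_shift,
            self.sbs1_weight,
            self.phase_switch_rate,
        )
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ValueError("fractions must lie in [0, 1]")
        if not 0.0 <= self.cnloh_maf <= 0.5:
            raise ValueError("cnloh_maf must lie in [0, 0.5]")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive (zero depth rejected)")
        for t in self.topologies():
            TopologyType(t)  # raises on out-of-range values

    def topologies(self) -> tuple[str, ...]:
        if isinstance(self.topology_types, str):
            return (self.topology_types,) * self.n_cases
        tt = tuple(self.topology_types)
        if len(tt) >= self.n_cases:
            return tt[: self.n_cases]
        return tuple(tt[i % len(tt)] for i in range(self.n_cases))


@dataclass
class CaseBundle:
    case_id: str
    topology_type: str
    roles: tuple[str, ...]
    variants: pd.DataFrame
    segments: pd.DataFrame


@dataclass
class TruthLedger:
    cases: pd.DataFrame  # case_id, topology_type
    variants: pd.DataFrame  # case_id, chrom, pos, ref, alt, branch, planted, gene
    segments: pd.DataFrame  # per emitted segment: true event type + haplotype
    genes: pd.DataFrame  # gene, planted_driver, planted_passenger


# ---------------------------------------------------------------------------
# cohort-level planting plans (deterministic functions of the config)


def _driver_plan(config: SimConfig, gene_table: pd.DataFrame) -> list[dict]:
    """Planted drivers: gene, role, CNA mechanism and the cases carrying a
    qualifying short variant.  Drivers 1-3 additionally carry a plausible
    copy-number event (CN-LOH with phased LoF, oncogene gain, TSG loss)."""
    tsg = gene_table.loc[gene_table["role"] == "TSG", "gene"].tolist()
    onc = gene_table.loc[gene_table["role"] == "ONCOGENE", "gene"].tolist()
    plan = []
    t_i = o_i = 0
    for i in range(config.n_planted_drivers):
        mech = {0: "CNLOH", 1: "GAIN", 2: "LOSS"}.get(i)
        role = "ONCOGENE" if mech == "GAIN" or (mech is None and i % 2 == 1) else "TSG"
        if role == "TSG":
            gene = tsg[t_i]
            t_i += 1
        else:
            gene = onc[o_i]
            o_i += 1
        n_sv = 3 if (mech is None and i % 2 == 1) else 2
        n_sv = min(n_sv, max(config.n_cases, 1))
        cases = sorted({(i + 2 * k) % config.n_cases for k in range(n_sv)})
        plan.append(
            {
                "gene": gene,
                "role": role,
                "mech": mech,
                "sv_cases": cases,
                "cna_case": cases[0] if mech else None,
            }
        )
    return plan


def _passenger_plan(config: SimConfig, gene_table: pd.DataFrame, drivers: list[dict]) -> list[dict]:
    """Planted passengers: at most one case with a qualifying variant each
    (every third passenger gets none at all)."""
    taken = {d["gene"] for d in drivers}
    remaining = [g for g in gene_table["gene"] if g not in taken]
    if config.n_passenger_genes > len(remaining):
        raise ValueError("gene table too small for requested passenger count")
    plan = []
    for j, gene in enumerate(remaining[: config.n_passenger_genes]):
        case = None if j % 3 == 2 else j % config.n_cases
        plan.append({"gene": gene, "sv_case": case})
    return plan


# ---------------------------------------------------------------------------
# substitution-class machinery


def _class_triples() -> list[tuple[str, str, str]]:
    """(ref, alt, context) on the pyrimidine strand for each of the 96 classes."""
    out = []
    for label in CONTEXTS_96:
        five, rest = label[0], label[2:]
        ref, alt, three = rest[0], rest[2], rest[4]
        out.append((ref, alt, five + ref + three))
    return out


_TRIPLES = _class_triples()


from functools import lru_cache


@lru_cache(maxsize=None)
def _mixture_probs(sbs1_weight: float) -> np.ndarray:
    ref = load_reference()
    p = sbs1_weight * ref["SBS1"].to_numpy() + (1.0 - sbs1_weight) * ref["flat"].to_numpy()
    return p / p.sum()


def _draw_alleles(rng: np.random.Generator, probs: np.ndarray, n: int):
    """Draw n SNVs from the 96-class mixture; half are emitted in their
    purine-strand representation to exercise strand normalization."""
    classes = rng.choice(96, size=n, p=probs)
    flip = rng.random(n) < 0.5
    refs, alts, ctxs = [], [], []
    for c, f in zip(classes, flip):
        ref, alt, ctx = _TRIPLES[c]
        if f:
            ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
        refs.append(ref)
        alts.append(alt)
        ctxs.append(ctx)
    return refs, alts, ctxs


# ---------------------------------------------------------------------------
# per-case simulation


def _gene_lookup(gene_table: pd.DataFrame):
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for r in gene_table.itertuples(index=False):
        by_chrom.setdefault(r.chrom, []).append((int(r.start), int(r.end), r.gene))
    return by_chrom


def _gene_at(by_chrom, chrom: str, pos: int):
    for start, end, gene in by_chrom.get(chrom, []):
        if start <= pos <= end:
            return gene
    return None


def simulate_case(
    config: SimConfig, case_index: int, gene_table: pd.DataFrame | None = None
) -> tuple[CaseBundle, TruthLedger]:
    """Simulate one matched case; returns its sample bundle and truth ledger."""
    if not 0 <= case_index < config.n_cases:
        raise ValueError(f"case_index {case_index} outside [0, {config.n_cases})")
    if gene_table is None:
        gene_table = read_gene_table()
    rng = np.random.default_rng([config.seed, case_index])
    case_id = f"case{case_index + 1}"
    topology = config.topologies()[case_index]
    roles = tuple(
        r
        for r in ("Nm", "N", "L", "G")
        if r != "N" or case_index not in config.cases_without_normal_gland
    )
    lesions = [r for r in roles if r != "Nm"]
    chroms = [f"chr{i}" for i in range(1, config.chrom_count + 1)]
    by_chrom = _gene_lookup(gene_table)
    gene_rows = {r.gene: r for r in gene_table.itertuples(index=False)}
    drivers = _driver_plan(config, gene_table)
    passengers = _passenger_plan(config, gene_table, drivers)

    # ---- plan CNA events: (roles carrying it, chrom, start, end, type, hap, origin)
    events: list[dict] = []
    used_chroms: dict[str, set] = {r: set() for r in lesions}
    type_cycle = ("GAIN", "LOSS", "CNLOH")

    def place_background_event(carriers, etype, origin):
        free = [c for c in chroms if all(c not in used_chroms[r] for r in carriers)]
        chrom = free[int(rng.integers(len(free)))]
        start = int(rng.integers(_GENE_REGION_END + 1, config.chrom_length - 2_000_000))
        events.append(
            {
                "roles": tuple(carriers),
                "chrom": chrom,
                "start": start,
                "end": start + 1_999_999,
                "event_type": etype,
                "hap": int(rng.integers(2)),
                "origin": origin,
            }
        )
        for r in carriers:
            used_chroms[r].add(chrom)

    branch_pair = [r for r in BRANCH_OF_TYPE[topology] if r in roles]
    for j in range(config.n_shared_cna_events):
        if len(branch_pair) >= 2:
            place_background_event(branch_pair, type_cycle[(case_index + j) % 3], "shared")
    for role in lesions:
        for j in range(int(config.n_cna_events.get(role, 0))):
            place_background_event([role], type_cycle[(j + case_index) % 3], "private")
    for d in drivers:
        if d["cna_case"] == case_index and "G" in roles:
            g = gene_rows[d["gene"]]
            events.append(
                {
                    "roles": ("G",),
                    "chrom": g.chrom,
                    "start": max(1, int(g.start) - 100_000),
                    "end": int(g.end) + 100_000,
                    "event_type": d["mech"],
                    "hap": int(rng.integers(2)),
                    "origin": f"driver:{d['gene']}",
                }
            )
            used_chroms["G"].add(g.chrom)

    # ---- plan variants: dicts carrying per-variant constants
    probs = _mixture_probs(config.sbs1_weight)
    variants: list[dict] = []

    def add_variants(n, carriers, branch, *, germline=False, planted=""):
        if n == 0:
            return
        vchrom = [chroms[i] for i in rng.integers(len(chroms), size=n)]
        vpos = rng.integers(1, config.chrom_length + 1, size=n)
        refs, alts, ctxs = _draw_alleles(rng, probs, n)
        for k in range(n):
            v = {
                "chrom": vchrom[k],
                "pos": int(vpos[k]),
                "ref": refs[k],
                "alt": alts[k],
                "context": ctxs[k],
                "carriers": tuple(carriers),
                "branch": branch,
                "planted": planted,
                "phase": None,
                "germline_zygosity": None,
                "evaf_override": None,
                "gene": None,
                "func_class": None,
                "pop_af": None,
            }
            if germline:
                het = rng.random() < 0.8
                v["germline_zygosity"] = "het" if het else "hom"
                v["phase"] = int(rng.integers(2)) if het else None
                v["pop_af"] = round(float(rng.uniform(0.01, 0.5)), 4)
            else:
                gene = _gene_at(by_chrom, v["chrom"], v["pos"])
                v["gene"] = gene
                if gene is None:
                    v["func_class"] = "intergenic"
                else:
                    v["func_class"] = rng.choice(
                        ["intronic", "exonic_syn", "UTR", "splicing"],
                        p=[0.6, 0.2, 0.15, 0.05],
                    )
                if rng.random() < 0.05:
                    v["pop_af"] = round(float(rng.uniform(0.01, 0.3)), 4)
            variants.append(v)

    add_variants(config.n_germline_variants, roles, "germline", germline=True)
    # phased hets planted inside every CNA event keep haplotype assignment informative
    for ev in events:
        for _ in range(config.n_phased_hets_per_event):
            pos = int(rng.integers(ev["start"], ev["end"] + 1))
            ref, alt, ctx = _TRIPLES[int(rng.choice(96, p=probs))]
            variants.append(
                {
                    "chrom": ev["chrom"],
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "context": ctx,
                    "carriers": roles,
                    "branch": "germline",
                    "planted": "",
                    "phase": int(rng.integers(2)),
                    "germline_zygosity": "het",
                    "evaf_override": None,
                    "gene": None,
                    "func_class": None,
                    "pop_af": round(float(rng.uniform(0.01, 0.5)), 4),
                }
            )
    add_variants(config.n_trunk_variants, lesions, "trunk")
    if len(branch_pair) >= 2:
        add_variants(config.n_shared_variants, branch_pair, "shared")
    for role in lesions:
        add_variants(config.n_private_variants, (role,), "private")

    # planted driver and passenger variants (carcinoma sample only)
    cnloh_events = {e["origin"]: e for e in events if e["origin"].startswith("driver:")}
    for d in drivers:
        if case_index not in d["sv_cases"] or "G" not in roles:
            continue
        g = gene_rows[d["gene"]]
        func = "stopgain" if d["role"] == "TSG" else "exonic_nonsyn"
        phase = None
        evaf = None
        if d["mech"] == "CNLOH" and d["cna_case"] == case_index:
            ev = cnloh_events[f"driver:{d['gene']}"]
            phase = 1 - ev["hap"]  # loss-of-function allele on the retained haplotype
            evaf = 0.7
        ref, alt, ctx = _TRIPLES[int(rng.choice(96, p=probs))]
        variants.append(
            {
                "chrom": g.chrom,
                "pos": int(rng.integers(g.start, g.end + 1)),
                "ref": ref,
                "alt": alt,
                "context": ctx,
                "carriers": ("G",),
                "branch": "private",
                "planted": "driver",
                "phase": phase,
                "germline_zygosity": None,
                "evaf_override": evaf,
                "gene": d["gene"],
                "func_class": func,
                "pop_af": None,
            }
        )
    for p in passengers:
        if p["sv_case"] != case_index or "G" not in roles:
            continue
        g = gene_rows[p["gene"]]
        ref, alt, ctx = _TRIPLES[int(rng.choice(96, p=probs))]
        variants.append(
            {
                "chrom": g.chrom,
                "pos": int(rng.integers(g.start, g.end + 1)),
                "ref": ref,
                "alt": alt,
                "context": ctx,
                "carriers": ("G",),
                "branch": "private",
                "planted": "passenger",
                "phase": None,
                "germline_zygosity": None,
                "evaf_override": None,
                "gene": p["gene"],
                "func_class": "exonic_nonsyn",
                "pop_af": None,
            }
        )

    # ---- emit variant rows (one per variant per carrier sample)
    events_by_role: dict[str, list[dict]] = {r: [] for r in roles}
    for ev in events:
        for r in ev["roles"]:
            events_by_role[r].append(ev)

    def overlapping_event(role, chrom, pos):
        for ev in events_by_role.get(role, []):
            if ev["chrom"] == chrom and ev["start"] <= pos <= ev["end"]:
                return ev
        return None

    rows = []
    evafs = []
    order = {r: i for i, r in enumerate(("Nm", "N", "L", "G"))}
    chrom_order = {c: i for i, c in enumerate(chroms)}
    variants.sort(key=lambda v: (chrom_order[v["chrom"]], v["pos"], v["ref"], v["alt"]))
    for v in variants:
        both_lg = "L" in v["carriers"] and "G" in v["carriers"]
        for role in sorted(v["carriers"], key=order.get):
            phase = v["phase"]
            if v["germline_zygosity"] is not None:
                evaf = 1.0 if v["germline_zygosity"] == "hom" else 0.5
                if phase is not None and role != "Nm":
                    ev = overlapping_event(role, v["chrom"], v["pos"])
                    if ev is not None:
                        if ev["event_type"] == "CNLOH":
                            evaf = (
                                config.cnloh_maf
                                if phase == ev["hap"]
                                else 1.0 - config.cnloh_maf
                            )
                        else:
                            lost, kept = _EVENT_HET_VAF[ev["event_type"]]
                            evaf = lost if phase == ev["hap"] else kept
            elif v["evaf_override"] is not None:
                evaf = v["evaf_override"]
            else:
                evaf = config.purity / 2.0
                if both_lg and role == "G":
                    evaf = min(1.0, evaf + config.vaf_shift)
            if phase is not None and config.phase_switch_rate > 0:
                if rng.random() < config.phase_switch_rate:
                    phase = 1 - phase
            rows.append(
                {
                    "case_id": case_id,
                    "sample_id": f"{case_id}_{role}",
                    "role": role,
                    "chrom": v["chrom"],
                    "pos": v["pos"],
                    "ref": v["ref"],
                    "alt": v["alt"],
                    "gene": v["gene"],
                    "func_class": v["func_class"],
                    "pop_af_eas": v["pop_af"],
                    "phase": phase,
                    "context": v["context"],
                }
            )
            evafs.append(evaf)
    evaf_arr = np.asarray(evafs)
    depth = np.maximum(1, rng.poisson(config.mean_depth, size=len(rows)))
    alt_reads = rng.binomial(depth, evaf_arr)
    bq = np.round(np.clip(rng.normal(33.0, 3.0, size=len(rows)), 2.0, 45.0), 1)
    variants_df = pd.DataFrame(rows)
    variants_df["depth"] = depth
    variants_df["alt_reads"] = alt_reads
    variants_df["vaf"] = np.round(alt_reads / depth, 6)
    variants_df["mean_base_quality"] = bq
    variants_df["phase"] = variants_df["phase"].astype("Int64")
    col_order = [
        "case_id", "sample_id", "role", "chrom", "pos", "ref", "alt",
        "depth", "alt_reads", "vaf", "gene", "func_class", "pop_af_eas",
        "phase", "mean_base_quality", "context",
    ]
    variants_df = variants_df[col_order]

    # ---- emit segments per sample (events carve neutral chromosomes)
    seg_rows = []
    truth_seg_rows = []
    for role in roles:
        sample_events = sorted(
            events_by_role.get(role, []), key=lambda e: (chrom_order[e["chrom"]], e["start"])
        )
        ev_by_chrom: dict[str, list[dict]] = {}
        for ev in sample_events:
            ev_by_chrom.setdefault(ev["chrom"], []).append(ev)
        for chrom in chroms:
            pieces = []
            cursor = 1
            for ev in ev_by_chrom.get(chrom, []):
                if ev["start"] > cursor:
                    pieces.append((cursor, ev["start"] - 1, None))
                pieces.append((ev["start"], ev["end"], ev))
                cursor = ev["end"] + 1
            if cursor <= config.chrom_length:
                pieces.append((cursor, config.chrom_length, None))
            for start, end, ev in pieces:
                n_probes = max(1, (end - start + 1) // 10_000)
                # segment-mean ratio noise shrinks with probe support; the
                # configured sigma applies at the 200-probe (2 Mb) scale
                ratio_sd = config.copy_ratio_sigma * min(1.0, np.sqrt(200.0 / n_probes))
                if ev is None:
                    ratio = rng.normal(1.0, ratio_sd)
                    maf = 0.5 - abs(rng.normal(0.0, config.maf_sigma))
                    etype, hap = "NEUTRAL", None
                elif ev["event_type"] == "GAIN":
                    ratio = rng.uniform(1.2, 1.5) + rng.normal(0.0, ratio_sd)
                    maf = 0.4 + rng.normal(0.0, 0.01)
                    etype, hap = "GAIN", ev["hap"]
                elif ev["event_type"] == "LOSS":
                    ratio = rng.uniform(0.6, 0.85) + rng.normal(0.0, ratio_sd)
                    maf = 0.35 + rng.normal(0.0, 0.01)
                    etype, hap = "LOSS", ev["hap"]
                else:  # CNLOH
                    ratio = 1.0 + rng.normal(0.0, ratio_sd)
                    maf = config.cnloh_maf + rng.normal(0.0, 0.01)
                    etype, hap = "CNLOH", ev["hap"]
                seg_rows.append(
                    {
                        "case_id": case_id,
                        "sample_id": f"{case_id}_{role}",
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "copy_ratio": round(max(0.0, float(ratio)), 6),
                        "minor_allele_fraction": round(float(np.clip(maf, 0.0, 0.5)), 6),
                        "n_probes": n_probes,
                    }
                )
                truth_seg_rows.append(
                    {
                        "case_id": case_id,
                        "sample_id": f"{case_id}_{role}",
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "event_type": etype,
                        "affected_haplotype": hap,
                        "origin": ev["origin"] if ev else "",
                    }
                )
    segments_df = pd.DataFrame(seg_rows)

    truth_var_rows = [
        {
            "case_id": case_id,
            "chrom": v["chrom"],
            "pos": v["pos"],
            "ref": v["ref"],
            "alt": v["alt"],
            "branch": v["branch"],
            "carriers": ",".join(v["carriers"]),
            "planted": v["planted"],
            "gene": v["gene"],
            "true_phase": v["phase"],
        }
        for v in variants
    ]
    truth = TruthLedger(
        cases=pd.DataFrame([{"case_id": case_id, "topology_type": topology}]),
        variants=pd.DataFrame(truth_var_rows),
        segments=pd.DataFrame(truth_seg_rows),
        genes=_truth_genes(config, gene_table),
    )
    bundle = CaseBundle(case_id, topology, roles, variants_df, segments_df)
    return bundle, truth


def _truth_genes(config: SimConfig, gene_table: pd.DataFrame) -> pd.DataFrame:
    drivers = {d["gene"] for d in _driver_plan(config, gene_table)}
    passengers = {p["gene"] for p in _passenger_plan(config, gene_table, _driver_plan(config, gene_table))}
    return pd.DataFrame(
        {
            "gene": gene_table["gene"],
            "planted_driver": gene_table["gene"].isin(drivers),
            "planted_passenger": gene_table["gene"].isin(passengers),
        }
    )


def simulate_cohort(
    config: SimConfig, gene_table: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLedger]:
    """Simulate all cases of the configured cohort; returns concatenated
    variant and segment tables plus the combined truth ledger."""
    if gene_table is None:
        gene_table = read_gene_table()
    if config.n_cases == 0:
        raise ValueError("cohort must contain at least one case")
    bundles, truths = [], []
    for i in range(config.n_cases):
        b, t = simulate_case(config, i, gene_table)
        bundles.append(b)
        truths.append(t)
    variants = pd.concat([b.variants for b in bundles], ignore_index=True)
    segments = pd.concat([b.segments for b in bundles], ignore_index=True)
    truth = TruthLedger(
        cases=pd.concat([t.cases for t in truths], ignore_index=True),
        variants=pd.concat([t.variants for t in truths], ignore_index=True),
        segments=pd.concat([t.segments for t in truths], ignore_index=True),
        genes=truths[0].genes if truths else _truth_genes(config, gene_table),
    )
    return variants, segments, truth


def simulate_spectrum(config: SimConfig, n_snvs: int, rng=None) -> np.ndarray:
    """Multinomial 96-context count vector from the SBS1/flat mixture."""
    if n_snvs < 0:
        raise ValueError("n_snvs must be non-negative")
    if rng is None:
        rng = np.random.default_rng([config.seed, 96])
    return rng.multinomial(n_snvs, _mixture_probs(config.sbs1_weight))


def write_cohort(config: SimConfig, out_dir, gene_table: pd.DataFrame | None = None) -> dict:
    """Simulate and write the cohort tables plus truth-ledger TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    variants, segments, truth = simulate_cohort(config, gene_table)
    write_variants(variants, out / "variants.tsv")
    write_segments(segments, out / "segments.tsv")
    truth.cases.to_csv(out / "truth_cases.tsv", sep="\t", index=False, na_rep="NA")
    truth.variants.to_csv(out / "truth_variants.tsv", sep="\t", index=False, na_rep="NA")
    truth.segments.to_csv(out / "truth_segments.tsv", sep="\t", index=False, na_rep="NA")
    truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False, na_rep="NA")
    return {
        "variants": out / "variants.tsv",
        "segments": out / "segments.tsv",
        "truth_cases": out / "truth_cases.tsv",
        "truth_variants": out / "truth_variants.tsv",
        "truth_segments": out / "truth_segments.tsv",
        "truth_genes": out / "truth_genes.tsv",
    }
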