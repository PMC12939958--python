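import numpy as np
import pandas as pd
import pytest

from lesionevo.io import read_gene_table
from lesionevo.synthetic_data import SimConfig, simulate_case, simulate_cohort


@pytest.fixture(scope="session")
def gene_table():
    return read_gene_table()


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def sim_case(default_config, gene_table):
    """One simulated TYPE1 case (bundle, truth)."""
    return simulate_case(default_config, 0, gene_table)


@pytest.fixture(scope="session")
def sim_cohort(default_config, gene_table):
    """Full default 7-case cohort (variants, segments, truth)."""
    return simulate_cohort(default_config, gene_table)


def make_variants(rows, **common):
    """Variant-table helper: list of dicts with sensible defaults filled in."""
    defaults = {
        "case_id": "case1",
        "sample_id": "case1_G",
        "role": "G",
        "chrom": "chr1",
        "pos": 100,
        "ref": "C",
        "alt": "T",
        "depth": 100,
        "alt_reads": 30,
        "vaf": 0.3,
        "gene": None,
        "func_class": "intergenic",
        "pop_af_eas": None,
        "phase": None,
    }
    defaults.update(common)
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        out.append(d)
    extra = sorted(set().union(*(r.keys() for r in rows)) - set(defaults)) if rows else []
    df = pd.DataFrame(out, columns=list(defaults) + extra)
    df["phase"] = pd.array(df["phase"], dtype="Int64")
    return df


def make_segments(rows, **common):
    defaults = {
        "case_id": "case1",
        "sample_id": "case1_G",
        "chrom": "chr1",
        "start": 1,
        "end": 1_000_000,
        "copy_ratio": 1.0,
        "minor_allele_fraction": 0.5,
        "n_probes": 100,
    }
    defaults.update(common)
    out = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        out.append(d)
    extra = sorted(set().union(*(r.keys() for r in rows)) - set(defaults)) if rows else []
    return pd.DataFrame(out, columns=list(defaults) + extra)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
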