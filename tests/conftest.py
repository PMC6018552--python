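import numpy as np
import pandas as pd
import pytest

from grnpipe import design

REF_GENES = ["ref1", "ref2"]


def plate_from_cq(cq_by_gene: dict[str, dict[tuple, float]],
                  ref_genes=tuple(REF_GENES)) -> pd.DataFrame:
    """Build a long-format plate from {gene: {(fin, region, stage, rep): cq}}."""
    rows = []
    for gene, cells in cq_by_gene.items():
        for (fin, region, stage, rep), cq in cells.items():
            rows.append(
                {
                    "gene": gene,
                    "fin": fin,
                    "region": region,
                    "stage": stage,
                    "replicate": rep,
                    "cq": cq,
                    "is_reference": gene in ref_genes,
                }
            )
    return pd.DataFrame(rows)


def full_design_samples(n_replicates=3):
    for fin in design.FINS:
        for region in design.regions_of(fin):
            for stage in design.STAGES:
                for rep in range(1, n_replicates + 1):
                    yield fin, region, stage, rep


def make_log_rq_table(values: dict[str, dict[tuple, float]]) -> pd.DataFrame:
    """Build a minimal RQ table (only log_rq is populated meaningfully)."""
    rows = []
    for gene, cells in values.items():
        for (fin, region, stage, rep), log_rq in cells.items():
            rows.append(
                {
                    "gene": gene,
                    "fin": fin,
                    "region": region,
                    "stage": stage,
                    "replicate": rep,
                    "log_rq": log_rq,
                    "rq": 2.0 ** log_rq,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ref_genes():
    return list(REF_GENES)
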