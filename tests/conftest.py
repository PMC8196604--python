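import numpy as np
import pytest

from ddgbench.variant_table import (
    Cmc,
    VariantDataset,
    VariantRecord,
    parse_variant_notation,
)


def make_record(protein_id, token, **kw):
    wt, pos, mut = parse_variant_notation(token)
    return VariantRecord(protein_id=protein_id, wt_aa=wt, position=pos,
                         mut_aa=mut, **kw)


def make_dataset(rows):
    """rows: iterable of (protein_id, token, kwargs)."""
    return VariantDataset(tuple(make_record(p, t, **kw) for p, t, kw in rows))


@pytest.fixture(scope="session")
def bench():
    """Study-shaped synthetic dataset: 164 variants, forced composition."""
    from ddgbench.synthetic_data import benchmark_dataset

    return benchmark_dataset(11)


@pytest.fixture()
def toy_dataset():
    return make_dataset([
        ("P1", "p.M17R", dict(ddg_exp=3.1, ddg_pred=2.5, patho_score=0.8,
                              rsa=0.1, f_wt=90.0, cmc=Cmc.TIER1)),
        ("P1", "p.A42G", dict(ddg_exp=0.4, ddg_pred=0.9, patho_score=0.3,
                              rsa=0.6, f_wt=30.0, cmc=Cmc.OTHER)),
        ("P2", "p.R38M", dict(ddg_exp=2.5, ddg_pred=3.4, patho_score=0.7,
                              rsa=0.15, f_wt=75.0, cmc=Cmc.TIER2,
                              is_predictor_training=True)),
        ("P2", "p.G5V", dict(ddg_exp=1.0, ddg_pred=0.2, patho_score=0.5,
                             rsa=0.4, f_wt=55.0, cmc=Cmc.OTHER)),
        ("P2", "p.L9P", dict(ddg_exp=None, ddg_pred=1.1, patho_score=0.4,
                             rsa=0.3, f_wt=20.0)),
    ])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
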