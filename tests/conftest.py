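import numpy as np
import pytest

from mrlink.sumstats import HarmonizedInstrumentSet, SumstatsTable, VariantAssociation


def make_hset(beta_x, se_x, beta_y, se_y, outcome_trait_type="continuous"):
    """Build a harmonized set directly from effect arrays."""
    beta_x = np.asarray(beta_x, dtype=float)
    return HarmonizedInstrumentSet(
        exposure_name="X",
        outcome_name="Y",
        variant_ids=[f"rs{i}" for i in range(len(beta_x))],
        beta_exposure=beta_x,
        se_exposure=np.broadcast_to(np.asarray(se_x, dtype=float), beta_x.shape).copy(),
        beta_outcome=np.asarray(beta_y, dtype=float),
        se_outcome=np.broadcast_to(np.asarray(se_y, dtype=float), beta_x.shape).copy(),
        outcome_trait_type=outcome_trait_type,
    )


def make_table(name, rows, trait_type="continuous"):
    """rows: iterable of (variant_id, ea, oa, beta, se, pval[, eaf])."""
    recs = []
    for row in rows:
        vid, ea, oa, beta, se, pval = row[:6]
        eaf = row[6] if len(row) > 6 else 0.3
        recs.append(
            VariantAssociation(
                variant_id=vid, effect_allele=ea, other_allele=oa,
                beta=beta, se=se, pval=pval, eaf=eaf,
            )
        )
    return SumstatsTable.from_records(name, trait_type, recs)


@pytest.fixture
def rng():
    return np.random.default_rng(20230928)
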