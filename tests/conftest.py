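import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ironmr.summary_data import (
    HarmonizedInstrument,
    InstrumentSet,
    OutcomeSet,
    VariantAssociation,
    associations_from_frame,
    build_instrument,
    harmonize,
    orient_to_exposure_increasing,
)


@pytest.fixture
def three_snp_instrument() -> HarmonizedInstrument:
    """A strong, already-oriented 3-SNP instrument."""
    return HarmonizedInstrument(
        rsids=["rs1800562", "rs1799945", "rs855791"],
        gamma=np.array([0.33, 0.19, 0.18]),
        se_gamma=np.array([0.009, 0.006, 0.005]),
        Gamma=np.array([0.0021, 0.0009, 0.0012]),
        se_Gamma=np.array([0.0007, 0.0006, 0.0006]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20201026)


def harmonized_from_tables(exp_df, out_df, direction=True, policy=None):
    """Shared helper: generator tables -> oriented HarmonizedInstrument."""
    instrument = build_instrument(
        "exposure", direction, associations_from_frame(exp_df), list(exp_df["rsid"])
    )
    outcome = OutcomeSet.from_associations("outcome", associations_from_frame(out_df))
    return orient_to_exposure_increasing(harmonize(instrument, outcome, policy))


def make_variant(rsid="rs1", ea="A", oa="G", beta=0.3, se=0.01, eaf=None, **kw):
    return VariantAssociation(rsid, ea, oa, beta, se, eaf=eaf, **kw)
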