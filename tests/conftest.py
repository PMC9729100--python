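import numpy as np
import pytest

from crisprselect import AmpliconContext
from crisprselect.fixtures import design_fixtures


@pytest.fixture(scope="session")
def design_battery():
    """20 designable synthetic SNV fixtures (locus, variant, cassette)."""
    return design_fixtures(20, seed=101)


@pytest.fixture(scope="session")
def one_cassette(design_battery):
    return design_battery[0]


@pytest.fixture(scope="session")
def toy_ctx():
    """A hand-built 60-nt amplicon context for exhaustive classifier checks.

    Variant site at position 30, WT' at 33, quantification window [20, 40),
    fully coding.
    """
    rng = np.random.default_rng(42)
    ref = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
    v_pos, w_pos = 30, 33
    v_alt = "ACGT"[("ACGT".index(ref[v_pos]) + 1) % 4]
    w_alt = "ACGT"[("ACGT".index(ref[w_pos]) + 1) % 4]
    return AmpliconContext(
        reference=ref,
        variant_sites=((v_pos, ref[v_pos], v_alt),),
        wtprime_sites=((w_pos, ref[w_pos], w_alt),),
        window=(20, 40),
        coding_intervals=((0, 60),),
    )
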