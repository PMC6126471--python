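import pytest

from barnyard.model import DropletCounts

# Worked examples for two-type mixing experiments: (N1, N2, N12) with the
# multiplet frequency each implies, to 3 decimals.  The first three are equal
# mixes (with the classical twice-cross-fraction shortcut alongside), the rest
# increasingly unequal mixes at fixed non-empty count.
EQUAL_MIX_EXAMPLES = [
    # (n1, n2, n12, multiplet_freq, twice_cross_fraction)
    (2005, 2005, 10, 0.005, 0.005),
    (2050, 2050, 100, 0.049, 0.050),
    (2500, 2500, 1000, 0.425, 0.500),
]

UNEQUAL_MIX_EXAMPLES = [
    # (n1, n2, n12, multiplet_freq)
    (2050, 2050, 100, 0.049),
    (3050, 1050, 100, 0.065),
    (3550, 550, 100, 0.110),
    (3850, 250, 100, 0.245),
    (3950, 150, 100, 0.459),
]

ALL_M_EXAMPLES = [(n1, n2, n12, m) for n1, n2, n12, m, _ in EQUAL_MIX_EXAMPLES] + (
    UNEQUAL_MIX_EXAMPLES
)


@pytest.fixture
def equal_mix_low_load() -> DropletCounts:
    """An equal-mix experiment at moderate loading (about 5% multiplets)."""
    return DropletCounts(n_type1=2050, n_type2=2050, n_mixed=100)
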