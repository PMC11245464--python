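import pytest

from cfn3 import read_counts


@pytest.fixture
def counts_curve_case():
    """Published count vector whose MLE lies on the theta2 = 0 curve."""
    return read_counts("17,5,27,5,16,5,19,6")


@pytest.fixture
def counts_face_case():
    """Published count vector whose MLE is the singleton with theta1 = 1."""
    return read_counts("21,12,9,8,7,11,17,15")


@pytest.fixture
def counts_interior_case():
    """A count vector with split collapse (40, 20, 25, 15): B in the interior region."""
    from cfn3.simulate import counts_from_split

    return counts_from_split((40, 20, 25, 15))
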