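import numpy as np
import pytest

from nacorr.isotopes import DEFAULT_ISOTOPES

# Printed single-label validation dataset: observed and corrected
# intensities of UDP-GlcNAc (C17H27N3O17P2) 13C isotopologues at counts
# 5..16 (zeros elsewhere), 13C natural abundance 0.01109.
UDP_GLCNAC_OBSERVED = {
    5: 187.9, 6: 60.5, 7: 109.8, 8: 418.4, 9: 23.1, 10: 165.0,
    11: 1438.0, 12: 1215.9, 13: 4235.8, 14: 1562.5, 15: 1253.9, 16: 175.8,
}
UDP_GLCNAC_CORRECTED = {
    5: 214.81, 6: 39.81, 7: 116.15, 8: 449.36, 9: 0.0, 10: 176.39,
    11: 1523.77, 12: 1183.78, 13: 4360.57, 14: 1420.73, 15: 1231.68,
    16: 149.9,
}
UDP_GLCNAC_NC = 17


@pytest.fixture
def c13():
    return DEFAULT_ISOTOPES["13C"]


@pytest.fixture
def n15():
    return DEFAULT_ISOTOPES["15N"]


@pytest.fixture
def udp_glcnac_vector():
    """Dense length-18 observed 13C intensity vector of UDP-GlcNAc."""
    v = np.zeros(UDP_GLCNAC_NC + 1)
    for count, intensity in UDP_GLCNAC_OBSERVED.items():
        v[count] = intensity
    return v
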