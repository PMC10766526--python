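"""Published reference coordinates for selected disease groups.

These are fixed numeric constants reproduced from a published
population-scale disease embedding (20 principal-component-rotated
dimensions).  They let downstream code and examples rank dimensions for a
well-characterized disease group without retraining anything.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ASTHMA_REFERENCE_COORDINATES"]

# Asthma disease-group loadings on the 20 rotated dimensions of the
# published reference space, in dimension order 1..20.
ASTHMA_REFERENCE_COORDINATES = np.array(
    [
        1.31,
        -0.452,
        -0.938,
        0.197,
        -1.30,
        -0.426,
        2.60,
        -1.26,
        0.994,
        -1.15,
        -0.373,
        0.969,
        0.781,
        -0.295,
        -1.42,
        -0.897,
        0.919,
        -0.350,
        -0.00992,
        0.00486,
    ]
)
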