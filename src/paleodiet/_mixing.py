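"""Shared two-source linear mixing arithmetic.

For a conservative tracer x measured in a consumer that is a binary mixture
of sources a (fraction ``1 - f``) and b (fraction ``f``)::

    x = (1 - f) * a + f * b          =>   f = (x - a) / (b - a)

First-order (delta-method) uncertainty with independent inputs:

    var(f) = (var(x) + (1 - f)^2 var(a) + f^2 var(b)) / (b - a)^2
"""

from __future__ import annotations

import math


def two_source_fraction(x: float, source_a: float, source_b: float) -> float:
    """Fraction of source ``b`` implied by the mixture value ``x``."""
    denom = source_b - source_a
    if denom == 0:
        raise ValueError("degenerate mixing model: equal source means")
    return (x - source_a) / denom


def two_source_sd(
    x_sd: float,
    source_a_sd: float,
    source_b_sd: float,
    f: float,
    denom: float,
) -> float:
    """First-order SD of the two-source fraction estimator."""
    if min(x_sd, source_a_sd, source_b_sd) < 0:
        raise ValueError("negative input SD")
    if denom == 0:
        raise ValueError("degenerate mixing model: equal source means")
    var = x_sd**2 + (1.0 - f) ** 2 * source_a_sd**2 + f**2 * source_b_sd**2
    return math.sqrt(var) / abs(denom)
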