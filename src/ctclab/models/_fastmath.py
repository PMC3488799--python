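"""Exponential evaluation for the model kernels.

All gate rates are built from exponentials, which dominate the cost of a
forward-Euler step.  ``exp_`` evaluates either the exact ``math.exp`` or an
opt-in fast approximation (range reduction to ``2**n * e**r`` with a 5th-order
polynomial on the remainder, |rel. err.| < 2e-7).  The flag is threaded as a
runtime argument so a single compiled kernel serves both modes; correctness
tests always run exact.
"""

import math

from numba import njit

_LOG2E = 1.4426950408889634
_LN2 = 0.6931471805599453


@njit(inline="always", cache=True)
def exp_(x: float, fast: bool) -> float:
    if not fast:
        return math.exp(x)
    if x < -700.0:
        return 0.0
    if x > 700.0:
        x = 700.0
    n = int(math.floor(x * _LOG2E + 0.5))
    r = x - n * _LN2
    p = 1.0 + r * (1.0 + r * (0.5 + r * (1.0 / 6.0 + r * (1.0 / 24.0 + r / 120.0))))
    return math.ldexp(p, n)
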