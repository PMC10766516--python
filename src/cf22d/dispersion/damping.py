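"""Zero-damping function of the C6 dispersion term.

f_d6(r) = 1 / (1 + 6 (r / (s_r6 R0))^(-14)): 0 at short range, 1 at long
range, 1/7 exactly at r = s_r6 R0.
"""

from __future__ import annotations

import numpy as np

__all__ = ["damping_factor"]


def damping_factor(r, r0, sr6):
    """Evaluate the zero-damping factor (element-wise on arrays).

    Parameters share one length unit (conventionally angstrom, matching the
    R0 tables); the factor is dimensionless.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0) or r0 <= 0 or sr6 <= 0:
        raise ValueError("r, r0 and sr6 must be positive")
    x = r / (sr6 * r0)
    out = 1.0 / (1.0 + 6.0 * x**-14)
    return out if out.ndim else float(out)
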