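"""Index bookkeeping for the nonseparable polynomial.

The a-coefficients are indexed by triples (i, j, k) with 0 <= i <= 3,
0 <= j <= 3 - i, 0 <= k <= 5 - i - j.  The lexicographic order returned by
:func:`enumerate_a_indices` is the canonical coefficient-file layout.
"""

from __future__ import annotations

from functools import lru_cache

__all__ = ["enumerate_a_indices", "N_A_TERMS", "N_B_TERMS", "N_C_TERMS", "N_DF_PARAMS"]


@lru_cache(maxsize=1)
def enumerate_a_indices() -> tuple[tuple[int, int, int], ...]:
    """All admissible (i, j, k) triples in lexicographic order."""
    return tuple(
        (i, j, k)
        for i in range(4)
        for j in range(4 - i)
        for k in range(6 - i - j)
    )


N_A_TERMS = len(enumerate_a_indices())  # 40
N_B_TERMS = 9
N_C_TERMS = 9
#: X plus the a/b/c coefficient blocks.
N_DF_PARAMS = 1 + N_A_TERMS + N_B_TERMS + N_C_TERMS
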