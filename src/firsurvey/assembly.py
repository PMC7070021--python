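"""Summary arithmetic for assembled scaffold sets.

The survey's assembly is characterized by a handful of length statistics
(total length, scaffold count, mean length, Nxx thresholds).  Only the
arithmetic lives here; the assembler itself is out of scope.
"""

from __future__ import annotations

import numpy as np


def mean_scaffold_length(total_bp: int, n_scaffolds: int) -> float:
    """Mean scaffold length in bp (total assembled length / count)."""
    if n_scaffolds < 1:
        raise ValueError("need at least one scaffold")
    if total_bp < 0:
        raise ValueError("total length must be >= 0")
    return total_bp / n_scaffolds


def n_statistic(lengths, fraction: float = 0.5) -> int:
    """Nxx length: the size at which ``fraction`` of total bases is reached.

    N50 is ``fraction=0.5``: the length L such that scaffolds >= L cover
    at least that fraction of the assembly.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0 or arr.sum() == 0:
        raise ValueError("need non-empty, non-zero lengths")
    target = arr.sum() * fraction
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, target)])


def scaffold_summary(lengths) -> dict:
    """Total size, counts and N50/N90 for a scaffold length list."""
    arr = np.asarray(lengths, dtype=np.int64)
    return {
        "total_bp": int(arr.sum()),
        "n_scaffolds": int(arr.size),
        "mean_bp": mean_scaffold_length(int(arr.sum()), int(arr.size)),
        "longest_bp": int(arr.max()),
        "n50_bp": n_statistic(arr, 0.5),
        "n90_bp": n_statistic(arr, 0.9),
        "n_ge_100bp": int((arr >= 100).sum()),
        "n_ge_2kb": int((arr >= 2000).sum()),
    }
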