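"""Flow-cytometry genome-size estimation against internal standards.

Nuclear DNA content of a sample is read off the ratio of its G0/1 peak
fluorescence to that of a co-processed reference standard of known 2C
value:

    sample 2C (pg) = (sample peak mean / standard peak mean) x standard 2C (pg)

and converted to base pairs with 1 pg = 0.978 x 10^9 bp (so 1C bp =
2C/2 x 0.978e9).  Replicates whose within-peak coefficient of variation
exceeds a threshold (default 5%) are excluded, the quality rule used on
the instrument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BP_PER_PG = 0.978e9


@dataclass
class CytometryRun:
    """Replicate peak intensities against one reference standard.

    ``replicates`` holds (sample_peak_mean, standard_peak_mean, peak_cv)
    triples; ``standard_2c_pg`` is the known 2C DNA content of the
    reference (e.g. barley 10.43 pg, Populus trichocarpa 0.98 pg).
    """

    standard_name: str
    standard_2c_pg: float
    replicates: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.standard_2c_pg <= 0:
            raise ValueError("standard 2C must be positive")
        for sample, std, cv in self.replicates:
            if sample <= 0 or std <= 0:
                raise ValueError("peak means must be positive")
            if cv < 0:
                raise ValueError("peak CV must be >= 0")


def replicate_2c(sample_peak: float, standard_peak: float, standard_2c_pg: float) -> float:
    """Single-replicate 2C value from the peak-intensity ratio."""
    if sample_peak <= 0 or standard_peak <= 0 or standard_2c_pg <= 0:
        raise ValueError("peaks and standard 2C must be positive")
    return sample_peak / standard_peak * standard_2c_pg


def estimate_2c(runs, cv_threshold: float = 0.05):
    """Pooled 2C estimate (mean, sd) over CV-filtered replicates.

    Replicates with ``peak_cv > cv_threshold`` are excluded; surviving
    per-replicate estimates are pooled with equal weight across all
    standards.  The sd is the sample standard deviation (ddof=1), 0.0 for
    a single surviving replicate.
    """
    if isinstance(runs, CytometryRun):
        runs = [runs]
    values = []
    for run in runs:
        for sample, std, cv in run.replicates:
            if cv > cv_threshold:
                continue
            values.append(replicate_2c(sample, std, run.standard_2c_pg))
    if not values:
        raise ValueError("all replicates excluded by the CV filter")
    values = np.asarray(values, float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def genome_size_from_2c(two_c_pg: float) -> int:
    """1C genome size in bp from a 2C value (pg), 1 pg = 0.978e9 bp."""
    if two_c_pg <= 0:
        raise ValueError("2C value must be positive")
    return int(round(two_c_pg / 2.0 * BP_PER_PG))


def pg_from_bp(one_c_bp: float) -> float:
    """1C DNA mass in pg from a 1C genome size in bp (inverse conversion)."""
    if one_c_bp <= 0:
        raise ValueError("genome size must be positive")
    return one_c_bp / BP_PER_PG
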