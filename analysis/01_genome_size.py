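#!/usr/bin/env python
"""Genome-size survey: flow-cytometry conversion and k-mer spectrum.

Part 1 reruns the published conversion chain on the printed quantities:
the sample/standard peak-intensity ratio against barley (2C = 10.43 pg),
the 1 pg = 0.978e9 bp conversion, and the 17-mer total / peak-depth
division.  Part 2 exercises the same estimators on a simulated diploid
spectrum with known truth, reporting recovery of genome size,
heterozygosity rate and repeat fraction.

Writes results/01_genome_size.tsv.
"""

from pathlib import Path

from firsurvey import cytometry, kmer
from firsurvey.containers import KmerHistogram
from firsurvey.synthetic import SpectrumTruth, gen_kmer_spectrum

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []

# --- published conversion chain -------------------------------------------
two_c = cytometry.replicate_2c(3.67e6, 1.38e6, 10.43)
rows.append(("single_replicate_2C_pg_vs_barley", round(two_c, 2)))
bp_pooled = cytometry.genome_size_from_2c(26.99)  # the pooled published 2C
rows.append(("pooled_2C_26.99pg_to_Gb", round(bp_pooled / 1e9, 2)))

total_17mers = 347_935_256_501
hist = KmerHistogram(17, {30: total_17mers // 30})
hist.counts[total_17mers - (total_17mers // 30) * 30] = 1
size = kmer.estimate_genome_size(hist, 30, error_depth_cutoff=1)
rows.append(("kmer_total/peak30_bp", size))

# --- simulated-spectrum recovery ------------------------------------------
truth = SpectrumTruth(
    genome_size_bp=10**6,
    heterozygosity=0.02,
    repeat_fraction=0.5,
    mean_depth=30,
    error_rate=0.01,
)
sim_hist = gen_kmer_spectrum(truth, seed=1)
peaks, main = kmer.find_peaks(sim_hist, prior_depth=truth.mean_depth)
est_size = kmer.estimate_genome_size(sim_hist, main)
signal = kmer.estimate_heterozygous_signal(sim_hist, main)
rep = kmer.estimate_repeat_fraction(sim_hist, main)
rate = kmer.calibrate_heterozygosity(
    signal, mean_depth=truth.mean_depth, repeat_fraction=rep
)
rows += [
    ("sim_truth_genome_bp", truth.genome_size_bp),
    ("sim_peak_depths", ";".join(str(d) for d, _ in peaks[:4])),
    ("sim_main_peak", main),
    ("sim_estimated_genome_bp", est_size),
    ("sim_genome_rel_error", round(est_size / truth.genome_size_bp - 1, 4)),
    ("sim_het_truth", truth.heterozygosity),
    ("sim_het_calibrated", round(rate, 4)),
    ("sim_repeat_truth", truth.repeat_fraction),
    ("sim_repeat_estimate", round(rep, 4)),
]

with open(OUT / "01_genome_size.tsv", "w") as fh:
    fh.write("quantity\tvalue\n")
    for name, value in rows:
        fh.write(f"{name}\t{value}\n")

for name, value in rows:
    print(f"{name}\t{value}")
print(f"\nA diploid spectrum with a half-depth shoulder yields a genome size "
      f"within {abs(est_size / truth.genome_size_bp - 1):.1%} of truth; "
      f"table written to {OUT / '01_genome_size.tsv'}")
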