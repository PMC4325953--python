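"""Genome-wide SSR summary statistics.

Shows the density/frequency arithmetic on published-scale counts (200,744
SSRs over 1,532 Mb of A-genome diploid cotton chromosomes) and then the
same summaries computed from a simulated genome.
"""

from ssrkit import (
    default_benchmark_spec,
    find_ssrs_genome,
    fold_ratio,
    relative_frequency,
    simulate_genome,
    summarize_genome,
)
from ssrkit.ssr_stats import MB, density_per_mb, round_half_up

# published-scale arithmetic
d = density_per_mb(200_744, 1_532 * MB)
print(f"200,744 SSRs / 1,532 Mb = {round_half_up(d)} SSR/Mb "
      f"(one SSR every {round_half_up(1000 / d)} kb)")
print(f"dinucleotide share: {round_half_up(relative_frequency(44_204, 200_744))} %")
print(f"AT vs AG abundance: {round_half_up(fold_ratio(38_855, 3_084), 1)}-fold")

# the same operations on a simulated genome
genome, _ = simulate_genome(default_benchmark_spec(seed=7))
summary = summarize_genome(find_ssrs_genome(genome), genome)
print(f"\nSimulated genome: {summary.total_count} SSRs on "
      f"{summary.total_length_mb:.3f} Mb "
      f"= {summary.overall_density:.1f} SSR/Mb")
print(summary.to_frame().to_string(index=False))
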