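"""Design PCR primers for chromosome-specific SSR loci.

Runs the full pipeline on a synthetic genome — detect, screen, then design
a primer pair for each chromosome-specific SSR under the marker-panel
constraints (17-27 bp primers, 125-250 bp product, Tm 60 +- 3 degC,
GC 20-80%).
"""

from ssrkit import (
    cross_chromosome_screen,
    default_benchmark_spec,
    design_primers,
    extract_all_flanks,
    find_ssrs_genome,
    simulate_genome,
)
from ssrkit.specificity import CHROMOSOME_SPECIFIC

genome, _ = simulate_genome(default_benchmark_spec(seed=2))
records = find_ssrs_genome(genome)
windows = extract_all_flanks(records, genome)
report = cross_chromosome_screen(windows)

specific = [w for w in windows if report.labels[w.ssr_id] == CHROMOSOME_SPECIFIC]
print(f"{len(specific)} chromosome-specific SSRs of {len(windows)} total\n")
for w in specific:
    pair = design_primers(w)
    if pair is None:
        print(f"{w.ssr_id}: no primer pair satisfies the constraints")
        continue
    print(f"{w.ssr_id}:")
    print(f"  F 5'-{pair.forward}-3'  Tm {pair.fwd_tm:.1f}  GC {pair.fwd_gc:.0f}%")
    print(f"  R 5'-{pair.reverse}-3'  Tm {pair.rev_tm:.1f}  GC {pair.rev_gc:.0f}%")
    print(f"  product {pair.product_size} bp, penalty {pair.penalty:.2f}")
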