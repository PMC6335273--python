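#!/usr/bin/env python
"""Step 1: generate the study's synthetic two-population world (seed 1).

Writes every input artifact (reference, gene models, VCF, QTLs, counts,
marked genes, ground truth) under results/world/ for the later steps.
"""

from pathlib import Path

from passcan.synthetic import SimConfig, simulate_world, write_world

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "world"


def main() -> None:
    config = SimConfig(seed=1)
    world = simulate_world(config)
    paths = write_world(world, OUT)
    print(f"world written under {OUT}")
    print(f"genome: {config.n_chroms} x {config.chrom_length / 1e6:.1f} Mb, "
          f"{len(world.sites)} variant sites, {len(world.genes)} genes")
    print("planted sweeps:")
    for chrom, s, e in world.truth.sweep_intervals:
        print(f"  {chrom}:{s}-{e} ({(e - s) / 1e3:.0f} kb)")
    print(f"planted DE genes: {len(world.truth.de_genes)}, "
          f"marked genes: {len(world.marked_genes)}")
    print(f"artifacts: {', '.join(p.name for p in paths.values())}")


if __name__ == "__main__":
    main()
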