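"""Simulate the in-silico experiment: reference bundle + four sRNA libraries.

Generates the default study conditions — 30 planted miRNAs (half copied into
the known-mature reference), ncRNA decoy loci, 60 transcripts with planted
target sites, and 2x50k-read pseudo-replicated libraries for two genotypes
under control and 100 mM NaCl — into results/data/.
"""

import sys
from pathlib import Path

from mirpipe.simulate import SimulationConfig, build_reference, simulate_libraries

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 7) -> None:
    cfg = SimulationConfig(seed=seed)
    bundle = build_reference(cfg, outdir=OUT / "reference")
    paths = simulate_libraries(bundle, cfg, outdir=OUT / "reads")
    n_known = sum(m.known for m in bundle.truth.mirnas.values())
    print(f"reference: {len(bundle.genome['chr1']):,} bp genome, "
          f"{len(bundle.truth.mirnas)} planted miRNAs ({n_known} known), "
          f"{len(bundle.annotation)} ncRNA loci, {len(bundle.transcripts)} transcripts")
    for lib in ("ST-CK", "ST-T", "SM-CK", "SM-T"):
        print(f"  {lib}: {len(paths[lib])} replicates x {cfg.reads_per_library:,} reads")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 7)
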