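#!/usr/bin/env python
"""Generate the synthetic study mitogenome: sequence, annotation, depth, truth.

Writes results/synthetic/{genome.fasta, annotations.gff3, depth.tsv,
truth.json}.  The genome mimics the architecture of an ORFan-carrying
spionid mitogenome: 13 protein-coding genes and 2 rRNAs on one strand,
tRNA punctuation with a duplicated trnM, three stop-free ORFan regions
(543, 1059, 426 nt) in intergenic positions, and an AT-rich stop-dense
control region.  Expression levels emulate the observed pattern: rRNAs
highest, PCGs and two ORFans comparable, the long ORFan transcribed in
two separate blocks, the control region nearly silent.
"""

import argparse
import json
from pathlib import Path

from mitorfan.core_io import write_depth, write_features_gff3
from mitorfan.synthetic_data import SimConfig, simulate_depth, \
    simulate_mitogenome

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main(seed: int = 11) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_mitogenome(SimConfig(seed=seed))

    with open(OUT / "genome.fasta", "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i:i + 70] + "\n")
    write_features_gff3(genome, OUT / "annotations.gff3")

    levels = {f.name: 60.0 for f in genome.features_of("PCG")}
    levels.update({f.name: 300.0 for f in genome.features_of("rRNA")})
    levels.update({f.name: 1.0 for f in genome.features_of("tRNA")})
    # short ORFans expressed like PCGs; the long one in two blocks only
    long_orfan = max(truth.orfans, key=lambda f: f.length)
    for f in truth.orfans:
        levels[f.name] = 1.0 if f is long_orfan else 60.0
    levels[truth.cr.name] = 1.0
    extra = []
    from mitorfan.core_io import Feature
    third = long_orfan.length // 3
    for k, (s, e) in enumerate([
            (long_orfan.start, long_orfan.start + third),
            (long_orfan.end - third, long_orfan.end)]):
        blk = Feature(f"{long_orfan.name}_block{k + 1}", "other", s, e, "+")
        extra.append(blk)
        levels[blk.name] = 60.0
    track = simulate_depth(genome, levels,
                           features=truth.all_features + extra,
                           background=1.0, seed=seed)
    write_depth(track, OUT / "depth.tsv")

    with open(OUT / "truth.json", "w") as fh:
        json.dump({
            "seed": seed,
            "genome_length": len(genome),
            "orfans": [{"name": f.name, "start": f.start, "end": f.end,
                        "strand": f.strand} for f in truth.orfans],
            "cr": {"start": truth.cr.start, "end": truth.cr.end},
            "two_block_orfan": long_orfan.name,
        }, fh, indent=2)

    print(f"simulated {len(genome)} nt circular genome with "
          f"{len(genome.features)} annotated features, "
          f"{len(truth.orfans)} hidden ORFans and a "
          f"{truth.cr.length} nt control region -> {OUT}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=11)
    main(ap.parse_args().seed)
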