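#!/usr/bin/env python
"""Sequence tracks, CAI and relative expression for the synthetic genome.

Reads results/synthetic/, computes windowed GC/skew tracks, per-feature
CAI against the all-PCG background, relative expression from the
simulated depth table, and transcript segmentation of the long ORFan
(which was simulated as two separate transcribed blocks).  Writes
results/{tracks.tsv, cai.tsv, expression.tsv}.
"""

import json
from pathlib import Path

import pandas as pd

from mitorfan.codon_usage import build_background, cai
from mitorfan.core_io import Feature, read_depth, read_features_gff3, \
    read_genome
from mitorfan.expression import feature_depth, transcript_segments
from mitorfan.seqstats import gc_content, skew

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    syn = BASE / "synthetic"
    genome = read_genome(syn / "genome.fasta", "fasta", circular=True)
    genome.features.extend(
        read_features_gff3(syn / "annotations.gff3", len(genome)))
    truth = json.loads((syn / "truth.json").read_text())
    orfans = [Feature(o["name"], "ORFan", o["start"], o["end"], o["strand"])
              for o in truth["orfans"]]

    # genome tracks
    gc = gc_content(genome.sequence, 100, 10, circular=True)
    at = skew(genome.sequence, "AT", 100, 10, circular=True)
    gcs = skew(genome.sequence, "GC", 100, 10, circular=True)
    tracks = pd.DataFrame({"position": gc.anchor, "gc_content": gc.values,
                           "at_skew": at.values, "gc_skew": gcs.values})
    tracks.to_csv(BASE / "tracks.tsv", sep="\t", index=False)

    # CAI with all PCGs as background
    pcg_seqs = []
    for f in genome.features_of("PCG"):
        s = genome.feature_seq(f)
        pcg_seqs.append(s[:3 * (len(s) // 3)])
    bg = build_background(pcg_seqs)
    cai_rows = []
    for f in genome.features_of("PCG") + orfans:
        s = genome.feature_seq(f)
        s = s[:3 * (len(s) // 3)]
        cai_rows.append({"gene": f.name, "ftype": f.ftype,
                         "n_codons": len(s) // 3, "CAI": cai(s, bg)})
    cai_df = pd.DataFrame(cai_rows)
    cai_df.to_csv(BASE / "cai.tsv", sep="\t", index=False)

    # expression; normalization is per-feature-mean over the listed set
    track = read_depth(syn / "depth.tsv", len(genome))
    feats = genome.features_of("PCG", "rRNA") + orfans
    expr = pd.DataFrame(
        [{"feature": e.name, "ftype": e.ftype, "mean_depth": e.mean_depth,
          "relative_level": e.relative_level}
         for e in feature_depth(track, feats)])
    expr.to_csv(BASE / "expression.tsv", sep="\t", index=False)

    long_orfan = next(f for f in orfans
                      if f.name == truth["two_block_orfan"])
    segs = transcript_segments(track, long_orfan, genome=genome)

    pcg_cai = cai_df[cai_df.ftype == "PCG"]["CAI"]
    orf_cai = cai_df[cai_df.ftype == "ORFan"]["CAI"]
    in_range = ((orf_cai >= pcg_cai.min()) & (orf_cai <= pcg_cai.max())).all()
    print(f"ORFan CAIs within the PCG range [{pcg_cai.min():.3f}, "
          f"{pcg_cai.max():.3f}]: {bool(in_range)}")
    rr = expr.groupby("ftype")["relative_level"].mean()
    print("mean relative expression by feature type:")
    print(rr.to_string())
    print(f"{long_orfan.name} transcribed in {len(segs)} separate "
          f"segment(s): {segs}")
    print(f"-> {BASE}/tracks.tsv, cai.tsv, expression.tsv")


if __name__ == "__main__":
    main()
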