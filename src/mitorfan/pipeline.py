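"""End-to-end orchestration: scan -> classify -> statistics -> report.

Driven by a single YAML config; partial inputs (no depth table, no
alignments) simply omit the corresponding report columns.  The run is
deterministic for a fixed seed and records enough metadata to re-run
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .codon_evol import CodonAlignment, compute_evol_stats
from .codon_usage import build_background, cai
from .core_io import Mitogenome, read_depth, read_genome, read_features_gff3, \
    write_features_gff3
from .expression import feature_depth
from .genetic_code import GeneticCode
from .orfan_scan import ScanConfig, control_region_candidates, find_orfans


@dataclass
class RunReport:
    """Joined per-locus table plus run metadata."""

    loci: pd.DataFrame
    metadata: Dict[str, object] = field(default_factory=dict)


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config_path: Path, out_dir: Optional[Path] = None) -> RunReport:
    """Run the full analysis described by a YAML config.

    Required key: ``genome`` (FASTA or GenBank path).  Optional keys:
    ``annotations`` (GFF3), ``depth`` (TSV), ``alignments`` (map of locus
    name -> aligned codon FASTA), ``scan`` (threshold overrides),
    ``seed``, ``table`` (NCBI genetic code id), ``circular``.
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        config = yaml.safe_load(fh) or {}
    if "genome" not in config:
        raise ValueError("config must name a 'genome' input")
    base = config_path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    seed = int(config.get("seed", 0))
    code = GeneticCode.from_ncbi(int(config.get("table", 5)))
    genome_path = resolve(config["genome"])
    fmt = "genbank" if genome_path.suffix in (".gb", ".gbk", ".genbank") \
        else "fasta"
    genome = read_genome(genome_path, fmt,
                         circular=bool(config.get("circular", True)))
    if "annotations" in config:
        genome.features.extend(
            read_features_gff3(resolve(config["annotations"]), len(genome)))

    scan_kwargs = config.get("scan", {}) or {}
    cfg = ScanConfig(**scan_kwargs)
    orfans = find_orfans(genome, code, cfg)
    crs = control_region_candidates(genome, code) \
        if genome.features_of("PCG") else []

    rows: List[dict] = []
    pcg_seqs = []
    for f in genome.features_of("PCG"):
        s = genome.feature_seq(f)
        pcg_seqs.append(s[:3 * (len(s) // 3)])
    bg = build_background(pcg_seqs, code) if pcg_seqs else None
    for f in orfans:
        row = {"locus": f.name, "ftype": "ORFan", "start": f.start,
               "end": f.end, "strand": f.strand,
               "frame": f.attributes.get("frame"),
               "length_nt": f.length,
               "provenance": f.attributes.get("provenance", "")}
        if bg is not None:
            seq = genome.feature_seq(f)
            row["cai"] = cai(seq[:3 * (len(seq) // 3)], bg, code)
        rows.append(row)
    for f in crs:
        rows.append({"locus": f.name, "ftype": "CR", "start": f.start,
                     "end": f.end, "strand": f.strand,
                     "length_nt": f.length, "provenance": "cr_heuristic"})

    loci = pd.DataFrame(rows)

    if "depth" in config and not loci.empty:
        track = read_depth(resolve(config["depth"]), len(genome))
        feats = genome.features_of("PCG", "rRNA") + orfans
        expr = {e.name: e.relative_level
                for e in feature_depth(track, feats)}
        loci["relative_expression"] = loci["locus"].map(expr)

    if "alignments" in config and not loci.empty:
        stats = {}
        for name, path in (config["alignments"] or {}).items():
            aln = CodonAlignment.from_fasta(resolve(path))
            stats[name] = compute_evol_stats(aln, code, seed=seed)
        for col in ("p_nt", "var_nt", "p_aa", "var_aa", "pS", "pN",
                    "dnds", "Z", "p_value"):
            loci[col] = loci["locus"].map(
                lambda n: getattr(stats[n], col) if n in stats else None)

    report = RunReport(loci=loci, metadata={
        "seed": seed, "config_hash": _config_hash(config),
        "mitorfan_version": __version__, "genome": genome.id,
        "genome_length": len(genome),
        "n_orfans": len(orfans), "n_cr_candidates": len(crs)})

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        annotated = Mitogenome(id=genome.id, sequence=genome.sequence,
                               circular=genome.circular,
                               features=genome.features + orfans + crs)
        write_features_gff3(annotated, out_dir / "features.gff3")
        loci.to_csv(out_dir / "loci.tsv", sep="\t", index=False)
        with open(out_dir / "report.json", "w") as fh:
            json.dump({"metadata": report.metadata,
                       "loci": loci.to_dict(orient="records")}, fh, indent=2,
                      default=str)
    return report
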