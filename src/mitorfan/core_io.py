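"""Input/output for mitogenomes, annotations and depth tables.

Internal convention: 0-based half-open intervals on the deposited forward
strand.  All serialized output (GFF3, BED) is 1-based inclusive per the
respective standards.  Features wrapping the circular origin carry a
``wraps`` flag and are exported as two GFF3 lines sharing an ``ID``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Union

import numpy as np
from Bio import SeqIO

FTYPES = ("PCG", "tRNA", "rRNA", "CR", "ORFan", "other")

_GENBANK_KEY_TO_FTYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                         "D-loop": "CR"}
_SO_TERM = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
            "CR": "region", "ORFan": "CDS", "other": "region"}


@dataclass
class Feature:
    """A typed genomic feature in 0-based half-open forward coordinates.

    A feature that wraps the circular origin is stored with
    ``start > end`` is *not* allowed; instead ``end`` may exceed the
    genome length and ``wraps`` is True, so that ``end - start`` is always
    the feature length (coordinates are taken mod L on extraction).
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "+"
    wraps: bool = False
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ftype not in FTYPES:
            raise ValueError(f"unknown ftype {self.ftype!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Mitogenome:
    """A (usually circular) mitochondrial genome with typed features."""

    id: str
    sequence: str
    circular: bool = True
    features: List[Feature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"invalid nucleotides: {sorted(bad)}")
        for f in self.features:
            self._check_feature(f)

    def _check_feature(self, f: Feature) -> None:
        n = len(self.sequence)
        if f.wraps:
            if not (f.start < n < f.end <= f.start + n):
                raise ValueError(f"bad wrapping feature {f.name}")
        elif f.end > n:
            raise ValueError(
                f"feature {f.name} end {f.end} exceeds genome length {n}")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_seq(self, f: Feature) -> str:
        """Feature nucleotide sequence on its own strand."""
        from .genetic_code import revcomp
        if f.wraps:
            s = self.sequence[f.start:] + self.sequence[:f.end - len(self)]
        else:
            s = self.sequence[f.start:f.end]
        return s if f.strand == "+" else revcomp(s)

    def features_of(self, *ftypes: str) -> List[Feature]:
        return [f for f in self.features if f.ftype in ftypes]


@dataclass
class DepthTrack:
    """Per-base read depth, 0-based, one value per genome position."""

    seqid: str
    depth: np.ndarray

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if (self.depth < 0).any():
            raise ValueError("negative depth values")


def read_genome(path: Union[str, Path], format: str = "fasta",
                circular: bool = True) -> Mitogenome:
    """Read a single-record FASTA or GenBank file into a :class:`Mitogenome`.

    GenBank features are mapped onto typed :class:`Feature` records
    (CDS -> PCG, tRNA -> tRNA, rRNA -> rRNA, D-loop -> CR); other keys are
    kept as ``other``.  FASTA carries no features.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise ValueError(f"failed to parse {path} as {format}: {exc}") from exc
    if len(records) == 0:
        raise ValueError(f"{path}: no sequence records found")
    if len(records) > 1:
        raise ValueError(f"{path}: expected single sequence, got {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper()
    if not seq:
        raise ValueError(f"{path}: empty sequence in record {rec.id}")
    features: List[Feature] = []
    if format == "genbank":
        n = len(seq)
        for feat in rec.features:
            if feat.type in ("source", "gene"):
                continue
            ftype = _GENBANK_KEY_TO_FTYPE.get(feat.type, "other")
            name = (feat.qualifiers.get("gene") or
                    feat.qualifiers.get("product") or
                    feat.qualifiers.get("locus_tag") or [feat.type])[0]
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            wraps = False
            parts = feat.location.parts
            if len(parts) == 2:  # origin-spanning join()
                p0, p1 = sorted(parts, key=lambda p: int(p.start))
                if int(p1.end) == n and int(p0.start) == 0:
                    start, end, wraps = int(p1.start), n + int(p0.end), True
            features.append(Feature(name=name, ftype=ftype, start=start,
                                    end=end, strand=strand, wraps=wraps))
    return Mitogenome(id=rec.id, sequence=seq, circular=circular,
                      features=features)


def read_depth(path: Union[str, Path], genome_length: int,
               seqid: Optional[str] = None) -> DepthTrack:
    """Read a samtools-depth-style TSV (seqid, 1-based pos, depth).

    Positions absent from the file get depth 0.  Internal storage is
    0-based.
    """
    depth = np.zeros(genome_length, dtype=np.int64)
    sid = seqid or ""
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected 3 tab-separated columns")
            s, pos_s, d_s = parts[0], parts[1], parts[2]
            pos, d = int(pos_s), int(d_s)
            if seqid is not None and s != seqid:
                continue
            sid = sid or s
            if pos < 1:
                raise ValueError(f"{path}:{ln}: positions are 1-based, got {pos}")
            if pos > genome_length:
                raise ValueError(
                    f"{path}:{ln}: position {pos} exceeds genome length "
                    f"{genome_length}")
            if d < 0:
                raise ValueError(f"{path}:{ln}: negative depth {d}")
            depth[pos - 1] = d
    return DepthTrack(seqid=sid or "unknown", depth=depth)


def write_depth(track: DepthTrack, path: Union[str, Path]) -> None:
    """Write a depth track as a 3-column TSV (seqid, 1-based pos, depth)."""
    with open(path, "w") as fh:
        for i, d in enumerate(track.depth):
            fh.write(f"{track.seqid}\t{i + 1}\t{int(d)}\n")


def _gff3_attrs(f: Feature) -> str:
    attrs = {"ID": f.name, "Name": f.name, "ftype": f.ftype}
    for k, v in f.attributes.items():
        attrs[k] = str(v)
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def write_features_gff3(genome: Mitogenome, path: Union[str, Path]) -> None:
    """Write features as GFF3 (1-based inclusive).

    Wrapping features become two lines sharing an ``ID`` attribute plus a
    ``wraps=1`` tag so the reader can reassemble them.
    """
    n = len(genome)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {n}\n")
        for f in genome.features:
            so = _SO_TERM[f.ftype]
            base = _gff3_attrs(f)
            if f.wraps:
                for (s, e) in ((f.start, n), (0, f.end - n)):
                    fh.write("\t".join([
                        genome.id, "mitorfan", so, str(s + 1), str(e),
                        ".", f.strand, ".", base + ";wraps=1"]) + "\n")
            else:
                fh.write("\t".join([
                    genome.id, "mitorfan", so, str(f.start + 1), str(f.end),
                    ".", f.strand, ".", base]) + "\n")


def read_features_gff3(path: Union[str, Path],
                       genome_length: Optional[int] = None) -> List[Feature]:
    """Read features from GFF3, reassembling two-part wrapping features."""
    rows: List[dict] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns")
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";") if kv)
            rows.append({
                "name": attrs.get("ID", attrs.get("Name", cols[2])),
                "so": cols[2], "start": int(cols[3]) - 1, "end": int(cols[4]),
                "strand": cols[6] if cols[6] in "+-" else "+",
                "attrs": attrs})
    out: List[Feature] = []
    seen: dict = {}
    for r in rows:
        attrs = r["attrs"]
        ftype = attrs.get("ftype")
        if ftype not in FTYPES:
            ftype = {"CDS": "PCG", "tRNA": "tRNA",
                     "rRNA": "rRNA"}.get(r["so"], "other")
        extra = {k: v for k, v in attrs.items()
                 if k not in ("ID", "Name", "ftype", "wraps")}
        if attrs.get("wraps") == "1":
            parts = seen.setdefault(r["name"], [])
            parts.append(r)
            if len(parts) == 2:
                p0, p1 = sorted(parts, key=lambda x: x["start"])
                if genome_length is None:
                    raise ValueError(
                        "genome_length required to reassemble wrapping features")
                out.append(Feature(name=r["name"], ftype=ftype,
                                   start=p1["start"],
                                   end=genome_length + p0["end"],
                                   strand=r["strand"], wraps=True,
                                   attributes=extra))
            continue
        out.append(Feature(name=r["name"], ftype=ftype, start=r["start"],
                           end=r["end"], strand=r["strand"],
                           attributes=extra))
    return out
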