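"""Six-frame stop-free region scanner and ORFan classification.

The scanner divides the genome into codons in all six reading frames under
the invertebrate mitochondrial code, locates in-frame stop codons, and
reports every maximal run of non-stop codons strictly between consecutive
stops.  Runs are filtered by a primary length threshold (360 nt), split at
tRNA gene boundaries, refiltered (210 nt), and the survivors in
unannotated territory become ORFan candidates.

Circular genomes are handled by the sequence-doubling technique: frames
are scanned over the doubled sequence and region lengths are capped at the
largest codon multiple not exceeding the genome length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .core_io import Feature, Mitogenome
from .genetic_code import GeneticCode, TABLE5, revcomp


@dataclass
class ScanConfig:
    """Thresholds for the stop-free region scan.

    min_len_primary is applied to raw run lengths before tRNA splitting;
    min_len_secondary after.  overlap_discard_frac is the fraction of a
    candidate's length that may overlap an annotated PCG/rRNA before it is
    discarded as a rediscovery of that gene.
    """

    min_len_primary: int = 360
    min_len_secondary: int = 210
    circular: bool = True
    mask_annotated: bool = True
    overlap_discard_frac: float = 0.5

    def __post_init__(self):
        if self.min_len_secondary > self.min_len_primary:
            raise ValueError("min_len_secondary must be <= min_len_primary")
        if self.min_len_primary <= 0 or self.min_len_secondary <= 0:
            raise ValueError("length thresholds must be positive")


@dataclass
class CandidateRegion:
    """A maximal in-frame stop-free interval.

    Coordinates are 0-based half-open on the forward strand; for wrapping
    regions ``end`` exceeds the genome length (mod-L semantics as for
    :class:`~mitorfan.core_io.Feature`).  ``frame`` is the codon phase in
    the scanned strand's own coordinates (revcomp coordinates for '-').
    """

    start: int
    end: int
    strand: str
    frame: int
    genome_length: int
    provenance: List[str] = field(default_factory=list)

    @property
    def length_nt(self) -> int:
        return self.end - self.start

    @property
    def wraps(self) -> bool:
        return self.end > self.genome_length

    def interval_mod(self) -> Tuple[int, int]:
        return self.start % self.genome_length, self.end % self.genome_length

    def sequence(self, genome: Mitogenome) -> str:
        """The region's nucleotide sequence read on its own strand."""
        n = len(genome)
        if self.wraps:
            s = genome.sequence[self.start:] + genome.sequence[:self.end - n]
        else:
            s = genome.sequence[self.start:self.end]
        return s if self.strand == "+" else revcomp(s)


def _runs_between_stops(scan: str, frame: int, code: GeneticCode,
                        L: int, circular: bool) -> List[Tuple[int, int]]:
    """Maximal stop-free runs in working coordinates of one frame/strand.

    For linear sequences the leading run (before the first stop) and the
    trailing run (after the last stop) are included, trimmed to whole
    codons.  For circular sequences ``scan`` is the doubled sequence (plus
    two bases) and the reading thread starting at ``frame`` is followed
    through both copies; every run is attributed to the frame of its
    opening codon, i.e. to the left-bounding stop lying in the first copy,
    so that across the three frame values each circular run is reported
    exactly once.  Run lengths are capped at the largest codon multiple
    not exceeding L; a frame devoid of stops yields one such capped run.
    """
    runs: List[Tuple[int, int]] = []
    cap = 3 * (L // 3)
    if circular:
        stops = [p for p in range(frame, 2 * L, 3)
                 if code.is_stop(scan[p:p + 3])]
        if not stops:
            return [(frame, frame + cap)]
        for i, a in enumerate(stops):
            if a >= L:
                break  # second-copy stop: run owned by another frame
            s = a + 3
            nxt = stops[i + 1] if i + 1 < len(stops) else None
            length = cap if nxt is None else min(nxt - s, cap)
            if length > 0:
                runs.append((s % L, s % L + length))
        return runs
    # linear: runs bounded by sequence ends as well as stops
    stops = [p for p in range(frame, len(scan) - 2, 3)
             if code.is_stop(scan[p:p + 3])]
    n_codons_end = frame + 3 * ((len(scan) - frame) // 3)
    bounds = [frame - 3] + stops + [n_codons_end]
    for a, b in zip(bounds, bounds[1:]):
        s, e = a + 3, b
        if e > s:
            runs.append((s, e))
    return runs


def stop_free_regions(genome: Mitogenome, code: GeneticCode = TABLE5,
                      cfg: Optional[ScanConfig] = None) -> List[CandidateRegion]:
    """All maximal stop-free runs >= the primary length threshold, six frames.

    Returns regions in forward-strand coordinates sorted by start.  Each
    region translated in its own frame contains no stop codon, and
    extending it by one codon hits a stop (or the sequence end / the
    circular cap).
    """
    cfg = cfg or ScanConfig()
    n = len(genome)
    if n < 3:
        raise ValueError("genome shorter than one codon")
    circular = cfg.circular and genome.circular
    out: List[CandidateRegion] = []
    for strand in "+-":
        work = genome.sequence if strand == "+" else revcomp(genome.sequence)
        scan = work + work + work[:2] if circular else work
        for frame in range(3):
            for (s, e) in _runs_between_stops(scan, frame, code, n, circular):
                if e - s < cfg.min_len_primary:
                    continue
                if strand == "-":
                    # reflect working (revcomp) coords back to forward
                    fs, fe = n - e, n - s
                    if fs < 0:  # wrapping region
                        fs += n
                        fe += n
                    region = CandidateRegion(fs, fe, "-", frame, n,
                                             ["primary_filter"])
                else:
                    region = CandidateRegion(s, e, "+", frame, n,
                                             ["primary_filter"])
                out.append(region)
    out.sort(key=lambda r: (r.start, r.end, r.strand, r.frame))
    return out


def _codon_anchor(region: CandidateRegion) -> Tuple[int, int]:
    """(anchor, direction) such that codon boundaries are anchor + 3k."""
    if region.strand == "+":
        return region.start, 1
    return region.end, -1


def _trim_to_frame(region: CandidateRegion, lo: int, hi: int
                   ) -> Optional[Tuple[int, int]]:
    """Trim [lo, hi) inward to in-frame codon boundaries of ``region``."""
    anchor, _ = _codon_anchor(region)
    # positions p with (p - anchor) % 3 == 0 are codon boundaries
    new_lo = lo + (-(lo - anchor)) % 3
    new_hi = hi - (hi - anchor) % 3
    if new_hi - new_lo < 3:
        return None
    return new_lo, new_hi


def split_by_trna(regions: List[CandidateRegion], genome: Mitogenome
                  ) -> List[CandidateRegion]:
    """Split regions at tRNA gene boundaries, trimming to codon boundaries.

    Each region intersecting one or more tRNA features is replaced by the
    sub-intervals outside the tRNAs; sub-intervals are trimmed inward so
    they remain whole in-frame codon runs (preserving the no-stop
    invariant).  Regions entirely inside a tRNA vanish.
    """
    n = len(genome)
    trnas = []
    for t in genome.features_of("tRNA"):
        trnas.append((t.start, t.end))
        # unrolled copy so wrapping regions see tRNAs past the origin
        trnas.append((t.start + n, t.end + n))
    trnas.sort()
    out: List[CandidateRegion] = []
    for region in regions:
        pieces = [(region.start, region.end)]
        cut = False
        for (ts, te) in trnas:
            nxt = []
            for (lo, hi) in pieces:
                if te <= lo or ts >= hi:
                    nxt.append((lo, hi))
                    continue
                cut = True
                if ts > lo:
                    nxt.append((lo, ts))
                if te < hi:
                    nxt.append((te, hi))
            pieces = nxt
        for (lo, hi) in pieces:
            trimmed = (lo, hi) if not cut else _trim_to_frame(region, lo, hi)
            if trimmed is None:
                continue
            lo2, hi2 = trimmed
            prov = region.provenance + (["trna_split"] if cut else [])
            out.append(CandidateRegion(lo2, hi2, region.strand, region.frame,
                                       n, prov))
    out.sort(key=lambda r: (r.start, r.end, r.strand, r.frame))
    return out


def secondary_filter(regions: List[CandidateRegion],
                     cfg: Optional[ScanConfig] = None) -> List[CandidateRegion]:
    """Keep regions with length >= the secondary threshold (210 nt)."""
    cfg = cfg or ScanConfig()
    out = []
    for r in regions:
        if r.length_nt >= cfg.min_len_secondary:
            out.append(CandidateRegion(r.start, r.end, r.strand, r.frame,
                                       r.genome_length,
                                       r.provenance + ["secondary_filter"]))
    return out


def _overlap_len(a: Tuple[int, int], b: Tuple[int, int], n: int) -> int:
    """Overlap of two possibly-wrapping intervals on a circle of size n."""
    def unroll(iv):
        s, e = iv
        return [(s, min(e, s + n))] if e <= n else [(s, n), (0, e - n)]
    tot = 0
    for (s1, e1) in unroll(a):
        for (s2, e2) in unroll(b):
            tot += max(0, min(e1, e2) - max(s1, s2))
    return tot


def classify_orfans(regions: List[CandidateRegion], genome: Mitogenome,
                    cfg: Optional[ScanConfig] = None) -> List[Feature]:
    """Discard rediscoveries of annotated genes, deduplicate, name survivors.

    Regions overlapping an annotated PCG or rRNA by more than
    ``overlap_discard_frac`` of their own length are dropped.  Remaining
    regions that overlap one another (any frame or strand) are clustered
    and the longest member of each cluster is kept, becoming an ORFan
    feature named by its length (``ORFan-544`` style).
    """
    cfg = cfg or ScanConfig()
    n = len(genome)
    annotated = [(f.start, f.end) for f in genome.features_of("PCG", "rRNA")]
    kept: List[CandidateRegion] = []
    for r in regions:
        ov = sum(_overlap_len((r.start, r.end), iv, n) for iv in annotated)
        if cfg.mask_annotated and ov > cfg.overlap_discard_frac * r.length_nt:
            continue
        kept.append(r)
    # cluster by positional overlap (union-find over pairs)
    parent = list(range(len(kept)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            if _overlap_len((kept[i].start, kept[i].end),
                            (kept[j].start, kept[j].end), n) > 0:
                parent[find(i)] = find(j)
    clusters: dict = {}
    for i, r in enumerate(kept):
        clusters.setdefault(find(i), []).append(r)
    features: List[Feature] = []
    for members in clusters.values():
        best = max(members, key=lambda r: (r.length_nt, -r.start))
        prov = best.provenance + ["cluster_kept"]
        features.append(Feature(
            name=f"ORFan-{best.length_nt}", ftype="ORFan",
            start=best.start, end=best.end, strand=best.strand,
            wraps=best.wraps,
            attributes={"frame": best.frame,
                        "provenance": ",".join(prov)}))
    features.sort(key=lambda f: f.start)
    return features


def find_orfans(genome: Mitogenome, code: GeneticCode = TABLE5,
                cfg: Optional[ScanConfig] = None) -> List[Feature]:
    """The full scan pipeline: scan, tRNA-split, refilter, classify."""
    cfg = cfg or ScanConfig()
    regions = stop_free_regions(genome, code, cfg)
    regions = split_by_trna(regions, genome)
    regions = secondary_filter(regions, cfg)
    return classify_orfans(regions, genome, cfg)


def _unannotated_intervals(genome: Mitogenome, min_len: int) -> List[Tuple[int, int]]:
    n = len(genome)
    covered = []
    for f in genome.features:
        if f.ftype in ("PCG", "tRNA", "rRNA"):
            if f.wraps:
                covered += [(f.start, n), (0, f.end - n)]
            else:
                covered.append((f.start, f.end))
    covered.sort()
    merged: List[List[int]] = []
    for s, e in covered:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = []
    prev = 0
    for s, e in merged:
        if s - prev >= min_len:
            gaps.append((prev, s))
        prev = max(prev, e)
    if n - prev >= min_len:
        gaps.append((prev, n))
    return gaps


def control_region_candidates(genome: Mitogenome, code: GeneticCode = TABLE5,
                              min_gap_len: int = 200) -> List[Feature]:
    """Heuristic control-region call: stop-dense in all six frames, low GC.

    Among unannotated intervals of at least ``min_gap_len`` nt that
    contain at least one in-frame stop in every one of the six reading
    frames, returns those whose GC content is strictly below the minimum
    GC over all annotated PCGs, ranked by ascending GC.
    """
    pcgs = genome.features_of("PCG")
    if not pcgs:
        raise ValueError("PCG annotation required for control-region calling")
    gaps = _unannotated_intervals(genome, min_gap_len)
    if not gaps:
        warnings.warn("no unannotated intervals of sufficient length")
        return []

    def gc(seq: str) -> float:
        acgt = sum(seq.count(b) for b in "ACGT")
        return (seq.count("G") + seq.count("C")) / acgt if acgt else 0.0

    min_pcg_gc = min(gc(genome.feature_seq(f)) for f in pcgs)
    cands = []
    for (s, e) in gaps:
        seq = genome.sequence[s:e]
        stop_in_all = all(
            any(code.is_stop((seq if st == "+" else revcomp(seq))[p:p + 3])
                for p in range(fr, len(seq) - 2, 3))
            for st in "+-" for fr in range(3))
        if not stop_in_all:
            continue
        g = gc(seq)
        if g < min_pcg_gc:
            cands.append((g, s, e))
    cands.sort()
    return [Feature(name=f"CR-candidate-{i + 1}", ftype="CR", start=s, end=e,
                    strand="+", attributes={"gc": f"{g:.4f}"})
            for i, (g, s, e) in enumerate(cands)]
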