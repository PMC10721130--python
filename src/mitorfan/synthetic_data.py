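"""Synthetic mitogenome and codon-evolution fixtures with known truth.

The genome generator emulates the architecture of a compact, circular,
single-coding-strand invertebrate mitogenome: 13 protein-coding genes and
2 rRNAs punctuated by tRNA genes (one tRNA duplicated, mirroring the
tRNA-Met duplication seen in ORFan-carrying spionids), an AT-rich control
region that contains stop codons in all six reading frames, and stop-free
ORFan regions embedded in intergenic positions.  Every inter-feature
junction carries a short stop cassette (TAA in all six frames on both
strands) so that stop-free runs never leak across feature boundaries and
the embedded ORFans are recoverable at their exact coordinates.

The codon-evolution generator runs a star-tree continuous-time codon
substitution process with tunable dN/dS (omega) and transition bias
(kappa); stop-creating changes have rate zero, so simulated regions stay
scanner-clean.  It is the parameter-recovery harness for the pairwise
selection statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import expm

from .codon_evol import CodonAlignment, _CODONS, _CODON_INDEX
from .core_io import DepthTrack, Feature, Mitogenome
from .genetic_code import GeneticCode, TABLE5, revcomp

#: 15-mer with a TAA stop in all three frames of both strands.
STOP_CASSETTE = "TAATTAATTAATTAA"

_TRNA_NAMES = ["trnM", "trnW", "trnC", "trnY", "trnL1", "trnL2", "trnK",
               "trnD", "trnG", "trnA", "trnR", "trnN", "trnS1", "trnS2",
               "trnE", "trnF", "trnH", "trnT", "trnP", "trnI", "trnQ",
               "trnV"]
_PCG_LENGTHS = [1536, 684, 1308, 780, 1371, 1632, 900, 1140, 297, 678,
                519, 159, 1119]  # cox1..atp8-like codon-multiple lengths
_PCG_NAMES = ["cox1", "cox2", "cox3", "atp6", "nad5", "nad4", "nad2",
              "cytb", "nad3", "nad1", "nad6", "atp8", "nad4l"]
_RRNA_LENGTHS = [950, 1200]


@dataclass
class SimConfig:
    """Parameters of the synthetic mitogenome."""

    genome_length: Optional[int] = None  # pad spacers toward this if set
    n_pcgs: int = 13
    n_trnas: int = 22
    duplicate_trna: bool = True  # a second trnM copy
    n_rrnas: int = 2
    orfan_specs: Sequence[Tuple[int, int]] = ((543, 4), (1059, 8), (426, 11))
    cr_length: int = 900
    cr_at_fraction: float = 0.85
    usage_bias: float = 1.0  # AT preference of the codon usage table
    min_len_primary: int = 360  # recovery guarantee scale for checks
    seed: int = 0

    def __post_init__(self):
        for (length, _) in self.orfan_specs:
            if length % 3 != 0:
                raise ValueError("ORFan lengths must be codon multiples")
        if not 0.0 <= self.cr_at_fraction <= 1.0:
            raise ValueError("cr_at_fraction must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated genome."""

    orfans: List[Feature]
    cr: Feature
    all_features: List[Feature]
    codon_weights: Dict[str, float]
    config: SimConfig


@dataclass
class EvolConfig:
    """Parameters of the star-tree codon-evolution process."""

    n_taxa: int = 5
    omega: float = 0.3
    branch_length: float = 0.5  # expected substitutions per codon site
    kappa: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError("omega must be nonnegative")
        if self.branch_length < 0:
            raise ValueError("branch_length must be nonnegative")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")


# ---------------------------------------------------------------------------
# genome generation
# ---------------------------------------------------------------------------

def _biased_codon_weights(code: GeneticCode, bias: float) -> Dict[str, float]:
    """AT-preferring sense-codon frequencies: w ~ exp(bias * #AT in codon)."""
    raw = {c: math.exp(bias * sum(b in "AT" for b in c))
           for c in code.sense_codons}
    tot = sum(raw.values())
    return {c: w / tot for c, w in raw.items()}


def random_coding_sequence(n_codons: int, weights: Dict[str, float],
                           rng: np.random.Generator,
                           start_codon: Optional[str] = "ATG") -> str:
    """A stop-free coding sequence drawn from a codon usage distribution."""
    codons = list(weights)
    p = np.array([weights[c] for c in codons])
    picks = rng.choice(len(codons), size=n_codons, p=p)
    seq = [codons[i] for i in picks]
    if start_codon and n_codons > 0:
        seq[0] = start_codon
    return "".join(seq)


def _at_rich(length: int, at_fraction: float, rng: np.random.Generator) -> str:
    p_at = at_fraction / 2
    p_gc = (1 - at_fraction) / 2
    return "".join(rng.choice(list("ATGC"),
                              p=[p_at, p_at, p_gc, p_gc], size=length))


def _max_stopfree_run(seq: str, code: GeneticCode) -> int:
    """Longest in-frame stop-free run (nt) over all 6 local frames."""
    best = 0
    for work in (seq, revcomp(seq)):
        for frame in range(3):
            run = 0
            for p in range(frame, len(work) - 2, 3):
                if code.is_stop(work[p:p + 3]):
                    run = 0
                else:
                    run += 3
                    best = max(best, run)
    return best


def _orfan_body(length: int, weights: Dict[str, float],
                rng: np.random.Generator, code: GeneticCode,
                max_other_run: int, retries: int = 100) -> str:
    """An ORFan sequence stop-free in frame 0 but stop-dense elsewhere.

    Resamples until no other frame (either strand) holds a stop-free run
    of ``max_other_run`` nt or more, so the embedded ORFan is the unique
    long candidate at its locus.
    """
    for _ in range(retries):
        body = random_coding_sequence(length // 3, weights, rng,
                                      start_codon="ATA")
        other = 0
        for shift in (1, 2):
            sub = body[shift:]
            other = max(other, _frame0_max_run(sub, code))
        rc = revcomp(body)
        for shift in (0, 1, 2):
            other = max(other, _frame0_max_run(rc[shift:], code))
        if other < max_other_run:
            return body
    raise RuntimeError("could not generate ORFan body within retry budget")


def _frame0_max_run(seq: str, code: GeneticCode) -> int:
    best = run = 0
    for p in range(0, len(seq) - 2, 3):
        if code.is_stop(seq[p:p + 3]):
            run = 0
        else:
            run += 3
            best = max(best, run)
    return best


def _control_region(cfg: SimConfig, rng: np.random.Generator,
                    code: GeneticCode, max_gc: float,
                    retries: int = 100) -> str:
    """AT-rich sequence with >=1 stop in all six frames and GC below max_gc."""
    for _ in range(retries):
        seq = _at_rich(cfg.cr_length, cfg.cr_at_fraction, rng)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        if gc >= max_gc:
            continue
        ok = all(
            any(code.is_stop((seq if st == "+" else revcomp(seq))[p:p + 3])
                for p in range(fr, len(seq) - 2, 3))
            for st in "+-" for fr in range(3))
        if ok:
            return seq
    raise RuntimeError("could not generate control region within retry budget")


def simulate_mitogenome(cfg: Optional[SimConfig] = None,
                        code: GeneticCode = TABLE5
                        ) -> Tuple[Mitogenome, SyntheticTruth]:
    """Generate one circular mitogenome-like sequence with known truth.

    The returned :class:`Mitogenome` carries only the PCG/tRNA/rRNA
    annotation (what a standard annotator would produce); the ORFan and
    control-region coordinates live in the :class:`SyntheticTruth`, so
    recovery tests are honest.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    weights = _biased_codon_weights(code, cfg.usage_bias)

    pcg_names = (_PCG_NAMES * ((cfg.n_pcgs // 13) + 1))[:cfg.n_pcgs]
    pcg_lengths = (_PCG_LENGTHS * ((cfg.n_pcgs // 13) + 1))[:cfg.n_pcgs]
    trna_names = (_TRNA_NAMES * ((cfg.n_trnas // 22) + 1))[:cfg.n_trnas]
    if cfg.duplicate_trna:
        trna_names = trna_names + ["trnM"]

    # interleave: each slot is (kind, name, payload length)
    slots: List[Tuple[str, str, int]] = []
    trna_iter = iter(trna_names)
    orfan_after = {pos: length for (length, pos) in cfg.orfan_specs}
    for i in range(cfg.n_pcgs):
        slots.append(("PCG", pcg_names[i], pcg_lengths[i]))
        if i in orfan_after:
            slots.append(("ORFan", f"orfan@{i}", orfan_after[i]))
        try:
            slots.append(("tRNA", next(trna_iter), 0))
        except StopIteration:
            pass
        if i == 1:  # rRNAs sit early in the gene order, tRNA-punctuated
            for r in range(cfg.n_rrnas):
                slots.append(("rRNA", f"rrn{'SL'[r % 2]}", _RRNA_LENGTHS[r % 2]))
                try:
                    slots.append(("tRNA", next(trna_iter), 0))
                except StopIteration:
                    pass
    for name in trna_iter:
        slots.append(("tRNA", name, 0))
    slots.append(("CR", "control_region", cfg.cr_length))

    # provisional GC floor of the coding set, used to steer the CR and to
    # keep ORFans from undercutting it: measured after generating PCGs
    parts: List[str] = []
    annotated: List[Feature] = []
    truth_features: List[Feature] = []
    orfans: List[Feature] = []
    pos = 0

    def emit(s: str):
        nonlocal pos
        parts.append(s)
        pos += len(s)

    pcg_seqs = {}
    for kind, name, length in slots:
        if kind == "PCG":
            pcg_seqs[name] = random_coding_sequence(length // 3, weights, rng)
    gc_vals = []
    for s in pcg_seqs.values():
        gc_vals.append((s.count("G") + s.count("C")) / len(s))
    min_pcg_gc = min(gc_vals)

    for kind, name, length in slots:
        emit(STOP_CASSETTE)
        if kind == "PCG":
            body = pcg_seqs[name] + "TAA"
            f = Feature(name=name, ftype="PCG", start=pos,
                        end=pos + len(body), strand="+")
            annotated.append(f)
            truth_features.append(f)
            emit(body)
        elif kind == "tRNA":
            body = _at_rich(int(rng.integers(60, 73)), 0.8, rng)
            f = Feature(name=name, ftype="tRNA", start=pos,
                        end=pos + len(body), strand="+")
            annotated.append(f)
            truth_features.append(f)
            emit(body)
        elif kind == "rRNA":
            body = _at_rich(length, 0.75, rng)
            f = Feature(name=name, ftype="rRNA", start=pos,
                        end=pos + len(body), strand="+")
            annotated.append(f)
            truth_features.append(f)
            emit(body)
        elif kind == "ORFan":
            # the intergenic gap around the ORFan includes ~36 nt of
            # zero-GC stop cassettes and flanking stops; require the
            # diluted gap GC to stay above the PCG floor so the locus is
            # never mistaken for a control region
            dilution = length / (length + 2 * len(STOP_CASSETTE) + 6)
            for attempt in range(100):
                body = _orfan_body(length, weights, rng, code,
                                   cfg.min_len_primary)
                gc = (body.count("G") + body.count("C")) / len(body)
                if gc * dilution > min_pcg_gc:
                    break
            else:
                raise RuntimeError("ORFan GC constraint unsatisfiable")
            emit("TAA")
            f = Feature(name=f"ORFan-{length}", ftype="ORFan", start=pos,
                        end=pos + length, strand="+",
                        attributes={"frame": pos % 3})
            orfans.append(f)
            truth_features.append(f)
            emit(body)
            emit("TAA")
        elif kind == "CR":
            body = _control_region(cfg, rng, code, max_gc=min_pcg_gc)
            emit(body)
    emit(STOP_CASSETTE)

    sequence = "".join(parts)
    if cfg.genome_length is not None:
        deficit = cfg.genome_length - len(sequence)
        if deficit < 0:
            raise ValueError(
                f"feature budget ({len(sequence)} nt) exceeds genome length "
                f"target {cfg.genome_length}")
        # pad after the terminal cassette in chunks below the CR-candidate
        # gap threshold, each chunk closed by a cassette
        pad = []
        while deficit > 0:
            chunk = min(deficit, 150)
            if chunk <= len(STOP_CASSETTE):
                pad.append(_at_rich(chunk, 0.8, rng))
                deficit = 0
            else:
                pad.append(_at_rich(chunk - len(STOP_CASSETTE), 0.8, rng))
                pad.append(STOP_CASSETTE)
                deficit -= chunk
        sequence += "".join(pad)

    # the truth control region is the whole terminal unannotated gap
    # (cassettes, AT-rich body and any padding), which is what an
    # annotation-complement CR caller can see
    cr_feature = Feature(name="control_region", ftype="CR",
                         start=annotated[-1].end, end=len(sequence),
                         strand="+")
    truth_features.append(cr_feature)

    genome = Mitogenome(id="synthetic_mitogenome", sequence=sequence,
                        circular=True, features=annotated)
    truth = SyntheticTruth(orfans=orfans, cr=cr_feature,
                           all_features=truth_features,
                           codon_weights=weights, config=cfg)
    return genome, truth


# ---------------------------------------------------------------------------
# codon evolution
# ---------------------------------------------------------------------------

def _codon_rate_matrix(code: GeneticCode, omega: float,
                       kappa: float) -> np.ndarray:
    """64x64 generator; stop rows/columns zero, scaled to 1 sub/codon/unit.

    Single-nucleotide exchangeabilities: transitions weighted kappa,
    transversions 1; nonsynonymous changes weighted omega; multi-nt and
    stop-involving changes have rate 0.  Scaling uses the uniform
    distribution over sense codons.
    """
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    n = 64
    Q = np.zeros((n, n))
    sense = [i for i, c in enumerate(_CODONS) if not code.is_stop(c)]
    sense_set = set(sense)
    for i in sense:
        ci = _CODONS[i]
        for pos in range(3):
            for b in "ACGT":
                if b == ci[pos]:
                    continue
                cj = ci[:pos] + b + ci[pos + 1:]
                j = _CODON_INDEX[cj]
                if j not in sense_set:
                    continue
                rate = kappa if (ci[pos], b) in transitions else 1.0
                if code.aa(ci) != code.aa(cj):
                    rate *= omega
                Q[i, j] = rate
    np.fill_diagonal(Q, 0.0)
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    mean_rate = -Q[sense, sense].mean()
    if mean_rate > 0:
        Q /= mean_rate
    return Q


def evolve_codon_alignment(ancestor: str,
                           cfg: Optional[EvolConfig] = None,
                           code: GeneticCode = TABLE5) -> CodonAlignment:
    """Evolve an ancestral coding sequence down a star tree.

    Each taxon is an independent draw from the codon transition matrix
    P = expm(Q * branch_length); rows stay aligned (no indels) and never
    contain stops.  omega = 0 keeps every row synonymous with the
    ancestor; branch_length = 0 returns identical rows.
    """
    cfg = cfg or EvolConfig()
    ancestor = ancestor.upper()
    if len(ancestor) % 3 != 0:
        raise ValueError("ancestor length not a multiple of 3")
    anc_idx = []
    for i in range(0, len(ancestor), 3):
        c = ancestor[i:i + 3]
        if code.is_stop(c):
            raise ValueError(f"ancestor contains stop codon {c} at nt {i}")
        anc_idx.append(_CODON_INDEX[c])
    anc_idx = np.array(anc_idx)
    rng = np.random.default_rng(cfg.seed)
    Q = _codon_rate_matrix(code, cfg.omega, cfg.kappa)
    P = expm(Q * cfg.branch_length)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    u = rng.random((cfg.n_taxa, len(anc_idx)))
    cum = np.cumsum(P, axis=1)
    cum_anc = cum[anc_idx]  # (n_codons, 64)
    picks = np.minimum((u[:, :, None] > cum_anc[None, :, :]).sum(axis=2), 63)
    rows = ["".join(_CODONS[i] for i in row) for row in picks]
    taxa = [f"taxon{t + 1}" for t in range(cfg.n_taxa)]
    return CodonAlignment(taxa=taxa, rows=rows)


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------

def simulate_depth(genome: Mitogenome, levels: Dict[str, float],
                   features: Optional[Sequence[Feature]] = None,
                   background: float = 0.5,
                   seed: Optional[int] = None) -> DepthTrack:
    """Poisson per-base depth: feature-specific means, background elsewhere.

    ``levels`` maps feature names to Poisson mean depths; features absent
    from the map get the background mean.  Later features overwrite
    earlier ones where they overlap.
    """
    if any(v < 0 for v in levels.values()):
        raise ValueError("expression levels must be nonnegative")
    rng = np.random.default_rng(seed)
    n = len(genome)
    mean = np.full(n, float(background))
    for f in (features if features is not None else genome.features):
        lam = float(levels.get(f.name, background))
        if f.wraps:
            mean[f.start:] = lam
            mean[:f.end - n] = lam
        else:
            mean[f.start:f.end] = lam
    depth = rng.poisson(mean)
    return DepthTrack(seqid=genome.id, depth=depth)
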