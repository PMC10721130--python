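"""Relative synonymous codon usage and the codon adaptation index.

The background usage table is pooled over all protein-coding genes of the
mitogenome set; RSCU follows the Sharp–Li convention (codon count over
the mean count of its synonymous family, with 0.5 pseudo-counts for
unobserved codons), and per-codon relative adaptiveness weights are
RSCU divided by the family maximum.  CAI of a gene is the geometric mean
of its codons' weights; codons in single-codon families are excluded
(under the invertebrate mitochondrial code no such family exists).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List

from .genetic_code import GeneticCode, TABLE5


def _families(code: GeneticCode) -> Dict[str, List[str]]:
    fams: Dict[str, List[str]] = {}
    for c in code.sense_codons:
        fams.setdefault(code.aa(c), []).append(c)
    return fams


@dataclass
class CodonUsageTable:
    """Pooled codon counts with derived RSCU and CAI weights."""

    counts: Dict[str, float]
    rscu: Dict[str, float] = field(default_factory=dict)
    weights: Dict[str, float] = field(default_factory=dict)


def build_background(genes: Iterable[str],
                     code: GeneticCode = TABLE5) -> CodonUsageTable:
    """Pool codon counts over genes and derive RSCU and weights.

    Each gene must have length divisible by 3; terminal stop codons are
    tolerated and skipped, internal stops raise.  Unobserved codons get a
    0.5 pseudo-count before RSCU so no weight is exactly zero; a family
    with no observations at all gets uniform weights 1 with a warning.
    """
    counts: Dict[str, float] = {c: 0.0 for c in code.sense_codons}
    for g, gene in enumerate(genes):
        gene = gene.upper()
        if len(gene) % 3 != 0:
            raise ValueError(f"gene {g}: length not a multiple of 3")
        n_codons = len(gene) // 3
        for i in range(n_codons):
            c = gene[3 * i:3 * i + 3]
            if code.is_stop(c):
                if i == n_codons - 1:
                    continue
                raise ValueError(f"gene {g}: internal stop {c} at codon {i}")
            if c in counts:
                counts[c] += 1
    rscu: Dict[str, float] = {}
    weights: Dict[str, float] = {}
    for aa, fam in _families(code).items():
        observed = sum(counts[c] for c in fam)
        if observed == 0:
            warnings.warn(f"family {aa} unobserved in background; weights 1")
            for c in fam:
                rscu[c] = 1.0
                weights[c] = 1.0
            continue
        eff = {c: (counts[c] if counts[c] > 0 else 0.5) for c in fam}
        mean = sum(eff.values()) / len(fam)
        for c in fam:
            rscu[c] = eff[c] / mean
        top = max(rscu[c] for c in fam)
        for c in fam:
            weights[c] = rscu[c] / top
    return CodonUsageTable(counts=counts, rscu=rscu, weights=weights)


def cai(gene: str, bg: CodonUsageTable,
        code: GeneticCode = TABLE5) -> float:
    """Codon adaptation index of one coding sequence against a background.

    Geometric mean of the gene's codon weights; a terminal stop codon is
    skipped, an internal stop raises, and codons in single-codon families
    would be excluded (none exist under table 5).
    """
    gene = gene.upper()
    if len(gene) % 3 != 0:
        raise ValueError("gene length not a multiple of 3")
    fams = _families(code)
    singletons = {fam[0] for fam in fams.values() if len(fam) == 1}
    log_sum = 0.0
    n = 0
    n_codons = len(gene) // 3
    for i in range(n_codons):
        c = gene[3 * i:3 * i + 3]
        if code.is_stop(c):
            if i == n_codons - 1:
                continue
            raise ValueError(f"internal stop codon {c} at codon {i}")
        if c in singletons or c not in bg.weights:
            continue
        log_sum += math.log(bg.weights[c])
        n += 1
    if n == 0:
        raise ValueError("no scorable codons in gene")
    return math.exp(log_sum / n)
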