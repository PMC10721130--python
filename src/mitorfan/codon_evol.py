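"""Pairwise evolutionary statistics on codon alignments.

Implements p-distances (nucleotide and amino-acid, pairwise deletion,
bootstrap variances), Nei–Gojobori synonymous/nonsynonymous site and
difference counting with equal-weight pathway averaging, the pooled
pN/pS ratio, and the codon-based Z-test of purifying selection
(H0: pN = pS vs H1: pN < pS) with bootstrap variance over codon columns.

Proportions are used without multiple-hit correction, and the ratio of
pooled sums over all pairs and columns is reported (not a mean of
per-pair ratios), matching the usual codon-based-test convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.stats import norm
from Bio import SeqIO

from .genetic_code import GeneticCode, TABLE5

_BASES = "ACGT"
_CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
_CODON_INDEX = {c: i for i, c in enumerate(_CODONS)}


@dataclass
class CodonAlignment:
    """Gap-aware aligned codon sequences over two or more taxa."""

    taxa: List[str]
    rows: List[str]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError("rows have unequal lengths")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError("alignment length not a multiple of 3")
        self.rows = [r.upper() for r in self.rows]
        for name, r in zip(self.taxa, self.rows):
            if set(r) <= {"-"}:
                raise ValueError(f"row {name} is all gaps")

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3

    def codon(self, row: int, col: int) -> str:
        return self.rows[row][3 * col:3 * col + 3]

    @classmethod
    def from_fasta(cls, path: Union[str, Path]) -> "CodonAlignment":
        taxa, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(taxa=taxa, rows=rows)

    def codon_index_matrix(self, code: GeneticCode) -> np.ndarray:
        """(n_taxa, n_codons) codon indices; -1 for gapped/ambiguous/stop.

        Stop codons are excluded from pairwise counting (the Nei–Gojobori
        site decomposition is undefined for them) and are treated like
        missing data, as a terminal stop would be.
        """
        m = np.full((len(self.rows), self.n_codons), -1, dtype=np.int64)
        for i, row in enumerate(self.rows):
            for j in range(self.n_codons):
                c = row[3 * j:3 * j + 3]
                idx = _CODON_INDEX.get(c, -1)
                if idx >= 0 and not code.is_stop(c):
                    m[i, j] = idx
        return m


@dataclass
class PairCounts:
    """Pooled Nei–Gojobori counts: sites (S, N) and differences (Sd, Nd)."""

    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0


@dataclass
class EvolStats:
    """The per-gene statistics bundle reported by the pipeline."""

    p_nt: float
    var_nt: float
    p_aa: float
    var_aa: float
    pS: float
    pN: float
    dnds: Optional[float]
    Z: Optional[float]
    p_value: Optional[float]
    flags: List[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Nei-Gojobori site and pathway counting
# ---------------------------------------------------------------------------

def ng_codon_sites(codon: str, code: GeneticCode = TABLE5) -> Tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one codon.

    At each of the three positions, the synonymous fraction is the number
    of synonymous single-nucleotide changes divided by the number of
    non-stop single-nucleotide changes (stop-creating changes are removed
    from the denominator).  s + n = 3 exactly.
    """
    codon = codon.upper()
    if code.is_stop(codon):
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa0 = code.aa(codon)
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if code.is_stop(mut):
                continue
            tot += 1
            if code.aa(mut) == aa0:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


def ng_pair_counts(codon1: str, codon2: str,
                   code: GeneticCode = TABLE5) -> Optional[Tuple[float, float]]:
    """(Sd, Nd) for one codon pair, averaged over mutational pathways.

    Codons differing at k positions are connected by k! orderings of the
    single-nucleotide changes; each ordering whose intermediates avoid
    stop codons contributes its synonymous/nonsynonymous step counts with
    equal weight.  Returns None (with a warning) in the rare case that
    every pathway passes through a stop.
    """
    c1, c2 = codon1.upper(), codon2.upper()
    if code.is_stop(c1) or code.is_stop(c2):
        raise ValueError("pair counting requires sense codons")
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    sd_tot = nd_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                ok = False
                break
            if code.aa(nxt) == code.aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            sd_tot += sd
            nd_tot += nd
            n_paths += 1
    if n_paths == 0:
        warnings.warn(f"all pathways between {c1} and {c2} pass through stops")
        return None
    return sd_tot / n_paths, nd_tot / n_paths


class _NGTables:
    """Precomputed per-codon sites and per-pair differences for one code."""

    def __init__(self, code: GeneticCode):
        self.site_s = np.full(64, np.nan)
        self.site_n = np.full(64, np.nan)
        for i, c in enumerate(_CODONS):
            if not code.is_stop(c):
                s, n = ng_codon_sites(c, code)
                self.site_s[i], self.site_n[i] = s, n
        self.pair_sd = np.full((64, 64), np.nan)
        self.pair_nd = np.full((64, 64), np.nan)
        for i, c1 in enumerate(_CODONS):
            if code.is_stop(c1):
                continue
            for j, c2 in enumerate(_CODONS):
                if code.is_stop(c2):
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = ng_pair_counts(c1, c2, code)
                if res is not None:
                    self.pair_sd[i, j], self.pair_nd[i, j] = res


_NG_CACHE: Dict[int, _NGTables] = {}


def _ng_tables(code: GeneticCode) -> _NGTables:
    if code.table_id not in _NG_CACHE:
        _NG_CACHE[code.table_id] = _NGTables(code)
    return _NG_CACHE[code.table_id]


def _column_counts(aln: CodonAlignment, code: GeneticCode
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-codon-column (Sd, Nd, S, N) pooled over all row pairs.

    A column contributes for a pair only when neither member is gapped,
    ambiguous or a stop (pairwise deletion), and when a pathway between
    the codons exists.
    """
    tab = _ng_tables(code)
    m = aln.codon_index_matrix(code)
    k, L = m.shape
    sd = np.zeros(L)
    nd = np.zeros(L)
    ss = np.zeros(L)
    nn = np.zeros(L)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = m[i], m[j]
            valid = (a >= 0) & (b >= 0)
            pa, pb = a[valid], b[valid]
            psd = tab.pair_sd[pa, pb]
            ok = ~np.isnan(psd)
            idx = np.flatnonzero(valid)[ok]
            sd[idx] += psd[ok]
            nd[idx] += tab.pair_nd[pa, pb][ok]
            ss[idx] += (tab.site_s[pa] + tab.site_s[pb])[ok] / 2.0
            nn[idx] += (tab.site_n[pa] + tab.site_n[pb])[ok] / 2.0
    return sd, nd, ss, nn


def dn_ds(aln: CodonAlignment, code: GeneticCode = TABLE5
          ) -> Tuple[float, float, Optional[float]]:
    """Pooled (pN, pS, pN/pS) over all pairs and ungapped codon columns.

    pS = sum(Sd)/sum(S), pN = sum(Nd)/sum(N); the ratio is None
    (undefined) when no synonymous difference was observed.
    """
    sd, nd, ss, nn = _column_counts(aln, code)
    S, N = ss.sum(), nn.sum()
    if S == 0 or N == 0:
        raise ValueError("no comparable codon columns in alignment")
    pS = sd.sum() / S
    pN = nd.sum() / N
    dnds = (pN / pS) if pS > 0 else None
    return pN, pS, dnds


def z_test_purifying(aln: CodonAlignment, code: GeneticCode = TABLE5,
                     reps: int = 500, seed: Optional[int] = None
                     ) -> Tuple[Optional[float], Optional[float]]:
    """Codon-based Z-test of purifying selection.

    Z = (pS - pN)/sqrt(Var(pS - pN)), with the variance estimated by
    bootstrap over codon columns (``reps`` replicates, seeded), and the
    one-tailed p-value from the upper normal tail.  Returns (None, None)
    when the test is undefined (no variation, zero bootstrap variance).
    """
    sd, nd, ss, nn = _column_counts(aln, code)
    S, N = ss.sum(), nn.sum()
    if S == 0 or N == 0:
        return None, None
    d_obs = sd.sum() / S - nd.sum() / N
    if not (sd.sum() + nd.sum()):
        return None, None  # identical rows: no variation to test
    rng = np.random.default_rng(seed)
    L = len(sd)
    idx = rng.integers(0, L, size=(reps, L))
    bs = sd[idx].sum(axis=1)
    bn = nd[idx].sum(axis=1)
    bS = ss[idx].sum(axis=1)
    bN = nn[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_star = np.where(bS > 0, bs / np.maximum(bS, 1e-300), 0.0) - \
            np.where(bN > 0, bn / np.maximum(bN, 1e-300), 0.0)
    var = float(np.var(d_star, ddof=1))
    if var <= 0:
        return None, None
    z = d_obs / np.sqrt(var)
    p = float(norm.sf(z))
    return float(z), p


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------

def _char_matrix(aln: CodonAlignment, level: str,
                 code: GeneticCode) -> np.ndarray:
    """Rows as per-column character codes; -1 marks gaps/ambiguity."""
    if level == "nt":
        arr = np.array([list(r) for r in aln.rows])
        codes = np.full(arr.shape, -1, dtype=np.int64)
        for v, b in enumerate(_BASES):
            codes[arr == b] = v
        return codes
    if level == "aa":
        rows = []
        for r in aln.rows:
            aa = []
            for j in range(0, len(r), 3):
                c = r[j:j + 3]
                if set(c) & {"-"} or any(b not in "ACGT" for b in c):
                    aa.append("-")
                else:
                    aa.append(code.aa(c))
            rows.append(aa)
        arr = np.array(rows)
        codes = np.full(arr.shape, -1, dtype=np.int64)
        letters = sorted(set(arr.ravel()) - {"-"})
        for v, b in enumerate(letters):
            codes[arr == b] = v
        return codes
    raise ValueError(f"level must be 'nt' or 'aa', got {level!r}")


def _mean_pairwise_p(codes: np.ndarray, cols: np.ndarray) -> Optional[float]:
    k = codes.shape[0]
    ds = []
    sub = codes[:, cols]
    for i in range(k):
        for j in range(i + 1, k):
            a, b = sub[i], sub[j]
            ok = (a >= 0) & (b >= 0)
            n_ok = int(ok.sum())
            if n_ok == 0:
                continue
            ds.append(float((a[ok] != b[ok]).sum()) / n_ok)
    if not ds:
        return None
    return float(np.mean(ds))


def p_distance(aln: CodonAlignment, level: str = "nt",
               bootstrap_reps: int = 500, seed: Optional[int] = None,
               code: GeneticCode = TABLE5) -> Tuple[float, float]:
    """Mean pairwise p-distance and its bootstrap variance.

    Pairwise deletion: a column counts for a pair only when neither row
    is gapped there.  The variance comes from resampling columns with
    replacement (``bootstrap_reps`` replicates, seeded); pairs with no
    comparable sites are excluded with a warning.
    """
    codes = _char_matrix(aln, level, code)
    L = codes.shape[1]
    k = codes.shape[0]
    # warn about incomparable pairs
    for i in range(k):
        for j in range(i + 1, k):
            if not ((codes[i] >= 0) & (codes[j] >= 0)).any():
                warnings.warn(
                    f"pair ({aln.taxa[i]}, {aln.taxa[j]}) has no comparable "
                    "sites; excluded")
    mean = _mean_pairwise_p(codes, np.arange(L))
    if mean is None:
        raise ValueError("no pair has comparable sites")
    rng = np.random.default_rng(seed)
    reps = []
    for _ in range(bootstrap_reps):
        cols = rng.integers(0, L, size=L)
        v = _mean_pairwise_p(codes, cols)
        if v is not None:
            reps.append(v)
    var = float(np.var(reps, ddof=1)) if len(reps) > 1 else 0.0
    return mean, var


def compute_evol_stats(aln: CodonAlignment, code: GeneticCode = TABLE5,
                       reps: int = 500, seed: Optional[int] = None) -> EvolStats:
    """All Fig-4-style statistics for one alignment, seeded and reproducible."""
    p_nt, var_nt = p_distance(aln, "nt", reps, seed, code)
    p_aa, var_aa = p_distance(aln, "aa", reps, None if seed is None
                              else seed + 1, code)
    pN, pS, dnds = dn_ds(aln, code)
    z, p = z_test_purifying(aln, code, reps, None if seed is None
                            else seed + 2)
    flags = []
    if dnds is None:
        flags.append("dnds_undefined")
    if z is None:
        flags.append("ztest_undefined")
    return EvolStats(p_nt=p_nt, var_nt=var_nt, p_aa=p_aa, var_aa=var_aa,
                     pS=pS, pN=pN, dnds=dnds, Z=z, p_value=p, flags=flags)
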