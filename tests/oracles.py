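"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own counting code: translation
goes through Biopython's Seq.translate, stop-free runs are found by
splitting protein strings on '*', and Nei-Gojobori pathway counts are
enumerated recursively.
"""

import itertools

from Bio.Seq import Seq


def translate5(seq: str) -> str:
    return str(Seq(seq).translate(table=5))


def oracle_stop_free_regions(seq: str, circular: bool, min_len: int):
    """Maximal in-frame stop-free runs >= min_len, all six frames.

    Returns a set of (start, end, strand, frame) in forward coordinates,
    using the same circular convention as the scanner (sequence doubling,
    run length capped at the largest codon multiple <= L, each circular
    run attributed to the frame of its opening codon) but implemented by
    translating and splitting protein strings rather than by stop-list
    arithmetic.
    """
    L = len(seq)
    cap = 3 * (L // 3)
    out = set()
    for strand in "+-":
        work = seq if strand == "+" else str(Seq(seq).reverse_complement())
        scan = work + work + work[:2] if circular else work
        for frame in range(3):
            usable = scan[frame:]
            usable = usable[: 3 * (len(usable) // 3)]
            prot = translate5(usable)
            if circular:
                stop_cods = [i for i, a in enumerate(prot) if a == "*"
                             and frame + 3 * i < 2 * L]
                if not stop_cods:
                    runs = [(frame, frame + cap)]
                else:
                    runs = []
                    for k, sc in enumerate(stop_cods):
                        start_nt = frame + 3 * sc + 3
                        if frame + 3 * sc >= L:
                            continue  # owned by another frame
                        if k + 1 < len(stop_cods):
                            gap = 3 * (stop_cods[k + 1] - sc - 1)
                            length = min(gap, cap)
                        else:
                            length = cap
                        if length > 0:
                            runs.append((start_nt % L, start_nt % L + length))
            else:
                runs = []
                pos = 0  # codon index
                for chunk in prot.split("*"):
                    if chunk:
                        runs.append((frame + 3 * pos,
                                     frame + 3 * (pos + len(chunk))))
                    pos += len(chunk) + 1
            for (s, e) in runs:
                if e - s < min_len:
                    continue
                if strand == "-":
                    fs, fe = L - e, L - s
                    if fs < 0:
                        fs, fe = fs + L, fe + L
                    out.add((fs, fe, "-", frame))
                else:
                    out.add((s, e, "+", frame))
    return out


def oracle_ng_sites(codon: str):
    """(s, n) by direct enumeration of the nine single-nt mutants."""
    aa0 = translate5(codon)
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if translate5(mut) == "*":
                continue
            tot += 1
            if translate5(mut) == aa0:
                syn += 1
        if tot:
            s += syn / tot
    return s, 3.0 - s


def oracle_ng_pair(c1: str, c2: str):
    """(Sd, Nd) by recursive pathway enumeration, stops excluded."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    paths = []

    def walk(cur, remaining, sd, nd):
        if not remaining:
            paths.append((sd, nd))
            return
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if translate5(nxt) == "*":
                continue
            step_syn = translate5(nxt) == translate5(cur)
            walk(nxt, remaining[:i] + remaining[i + 1:],
                 sd + (1 if step_syn else 0), nd + (0 if step_syn else 1))

    walk(c1, diff, 0, 0)
    if not paths:
        return None
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def all_two_diff_sense_pairs():
    codons = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
    sense = [c for c in codons if translate5(c) != "*"]
    for c1 in sense:
        for c2 in sense:
            if sum(a != b for a, b in zip(c1, c2)) == 2:
                yield c1, c2
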