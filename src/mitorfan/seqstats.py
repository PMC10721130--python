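"""Windowed sequence tracks: GC content, AT/GC skew, hydropathy, conservation.

These are the genome- and alignment-level descriptive tracks used to
characterize candidate regions: GC and skew profiles over the mitogenome
(circular windows supported), Kyte–Doolittle hydropathy over protein
sequences, and a modal-residue conservation score over amino-acid
alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

#: Kyte-Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


@dataclass
class WindowTrack:
    """A sliding-window statistic with window-center anchors."""

    window: int
    step: int
    values: np.ndarray
    anchor: np.ndarray
    flags: Optional[np.ndarray] = None  # True where denominator was zero


@dataclass
class ConservationTrack:
    """Per-column conservation scores in [0, 1] with optional smoothing."""

    scores: np.ndarray
    smooth_window: int


def _window_starts(L: int, window: int, step: int, circular: bool) -> np.ndarray:
    if circular:
        return np.arange(0, L, step)
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")
    return np.arange(0, L - window + 1, step)


def _window_seq(seq: str, start: int, window: int, circular: bool) -> str:
    L = len(seq)
    if circular and start + window > L:
        reps = (start + window) // L + 1
        return (seq * reps)[start:start + window]
    return seq[start:start + window]


def gc_content(seq: str, window: int = 100, step: int = 10,
               circular: bool = True) -> WindowTrack:
    """Windowed (G+C)/(A+C+G+T); N is excluded from both counts."""
    seq = seq.upper()
    starts = _window_starts(len(seq), window, step, circular)
    values = np.zeros(len(starts))
    flags = np.zeros(len(starts), dtype=bool)
    for i, s in enumerate(starts):
        w = _window_seq(seq, int(s), window, circular)
        acgt = sum(w.count(b) for b in "ACGT")
        if acgt == 0:
            flags[i] = True
            continue
        values[i] = (w.count("G") + w.count("C")) / acgt
    return WindowTrack(window=window, step=step, values=values,
                       anchor=(starts + window / 2) % max(len(seq), 1),
                       flags=flags)


def skew(seq: str, kind: str = "GC", window: int = 100, step: int = 10,
         circular: bool = True) -> WindowTrack:
    """Windowed AT skew (A-T)/(A+T) or GC skew (G-C)/(G+C).

    Windows whose denominator is zero get value 0 with the flag set.
    """
    if kind not in ("AT", "GC"):
        raise ValueError(f"kind must be 'AT' or 'GC', got {kind!r}")
    seq = seq.upper()
    x, y = ("A", "T") if kind == "AT" else ("G", "C")
    starts = _window_starts(len(seq), window, step, circular)
    values = np.zeros(len(starts))
    flags = np.zeros(len(starts), dtype=bool)
    for i, s in enumerate(starts):
        w = _window_seq(seq, int(s), window, circular)
        nx, ny = w.count(x), w.count(y)
        if nx + ny == 0:
            flags[i] = True
            continue
        values[i] = (nx - ny) / (nx + ny)
    return WindowTrack(window=window, step=step, values=values,
                       anchor=(starts + window / 2) % max(len(seq), 1),
                       flags=flags)


def hydropathy(protein: str, window: int = 9) -> WindowTrack:
    """Kyte-Doolittle sliding-mean hydropathy, anchored at window centers.

    The window must be odd and no longer than the sequence; residues
    outside the standard 20-letter alphabet (including '*') raise.
    """
    protein = protein.upper()
    if window % 2 == 0:
        raise ValueError("hydropathy window must be odd")
    if window > len(protein):
        raise ValueError("window exceeds protein length")
    bad = set(protein) - set(KYTE_DOOLITTLE)
    if bad:
        raise ValueError(f"unknown residues: {sorted(bad)}")
    vals = np.array([KYTE_DOOLITTLE[a] for a in protein])
    kernel = np.ones(window) / window
    means = np.convolve(vals, kernel, mode="valid")
    anchors = np.arange(window // 2, window // 2 + len(means))
    return WindowTrack(window=window, step=1, values=means, anchor=anchors)


def conservation(rows: List[str], smooth: int = 5) -> ConservationTrack:
    """Modal-residue conservation per alignment column, sliding-mean smoothed.

    Raw column score = frequency of the most common non-gap residue among
    non-gap rows; columns with more than 50% gaps score 0.  ``smooth``
    must be odd; 1 disables smoothing.
    """
    if not rows or len(rows) < 2:
        raise ValueError("alignment needs at least 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows have unequal lengths")
    if smooth % 2 == 0:
        raise ValueError("smoothing window must be odd")
    rows = [r.upper() for r in rows]
    k = len(rows)
    L = len(rows[0])
    raw = np.zeros(L)
    for j in range(L):
        col = [r[j] for r in rows if r[j] not in "-."]
        if not col or len(col) < k / 2:  # more than half the rows gapped
            continue
        counts = {}
        for a in col:
            counts[a] = counts.get(a, 0) + 1
        raw[j] = max(counts.values()) / len(col)
    if smooth > 1 and L >= smooth:
        kernel = np.ones(smooth) / smooth
        padded = np.pad(raw, smooth // 2, mode="edge")
        scores = np.convolve(padded, kernel, mode="valid")
    else:
        scores = raw
    return ConservationTrack(scores=scores, smooth_window=smooth)
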