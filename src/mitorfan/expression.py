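"""Per-feature relative expression from per-base cDNA read depth.

Expression of a feature is its mean per-base depth; relative level is
that mean divided by the average of the means over the normalization
feature set, so a uniformly covered genome gives every feature level 1.
Transcript segmentation locates sub-intervals of a feature with depth
above a fraction of the genome-wide mean coding-gene depth, used to
detect features transcribed in separate pieces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core_io import DepthTrack, Feature, Mitogenome


@dataclass
class FeatureExpression:
    name: str
    ftype: str
    length: int
    mean_depth: float
    relative_level: float


def _feature_depth_values(track: DepthTrack, f: Feature) -> np.ndarray:
    n = len(track.depth)
    if f.wraps:
        if not f.start < n:
            raise ValueError(f"feature {f.name} outside track")
        return np.concatenate([track.depth[f.start:], track.depth[:f.end - n]])
    if f.end > n:
        raise ValueError(f"feature {f.name} extends beyond track length {n}")
    return track.depth[f.start:f.end]


def feature_depth(track: DepthTrack, features: Sequence[Feature]
                  ) -> List[FeatureExpression]:
    """Mean depth and relative expression level per feature.

    relative_level = mean depth of the feature / mean of mean depths over
    the given feature set (per-feature-mean normalization, declared in
    output headers by the CLI).
    """
    if not features:
        return []
    means = [float(_feature_depth_values(track, f).mean()) for f in features]
    overall = float(np.mean(means))
    out = []
    for f, m in zip(features, means):
        rel = m / overall if overall > 0 else 0.0
        out.append(FeatureExpression(name=f.name, ftype=f.ftype,
                                     length=f.length, mean_depth=m,
                                     relative_level=rel))
    return out


def transcript_segments(track: DepthTrack, feature: Feature,
                        pcg_mean_depth: Optional[float] = None,
                        genome: Optional[Mitogenome] = None,
                        min_depth_frac: float = 0.1,
                        min_run: int = 50) -> List[Tuple[int, int]]:
    """Maximal well-covered runs within a feature.

    A position belongs to a segment when its depth is at least
    ``min_depth_frac`` times the genome-wide mean depth over annotated
    protein-coding genes (``pcg_mean_depth``; computed from ``genome``
    when not given).  Runs shorter than ``min_run`` nt are dropped.
    Returned intervals are 0-based half-open in forward coordinates
    (coordinates may exceed the genome length for wrapping features,
    mirroring the feature convention).
    """
    if pcg_mean_depth is None:
        if genome is None:
            raise ValueError("need pcg_mean_depth or an annotated genome")
        pcgs = genome.features_of("PCG")
        if not pcgs:
            raise ValueError("no PCG features to normalize against")
        pcg_mean_depth = float(np.mean(
            [float(_feature_depth_values(track, f).mean()) for f in pcgs]))
    threshold = min_depth_frac * pcg_mean_depth
    vals = _feature_depth_values(track, feature)
    above = vals >= threshold if threshold > 0 else vals > 0
    segments: List[Tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                segments.append((feature.start + start, feature.start + i))
            start = None
    if start is not None and len(above) - start >= min_run:
        segments.append((feature.start + start, feature.start + len(above)))
    return segments
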