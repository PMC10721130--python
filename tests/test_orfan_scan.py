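"""The stop-free region scanner, its filters and the CR heuristic."""

import numpy as np
import pytest

from mitorfan.core_io import Feature, Mitogenome
from mitorfan.orfan_scan import (CandidateRegion, ScanConfig, classify_orfans,
                                 control_region_candidates, find_orfans,
                                 secondary_filter, split_by_trna,
                                 stop_free_regions)
from mitorfan.genetic_code import TABLE5, revcomp, translate

from oracles import oracle_stop_free_regions


def _regions_as_set(regions):
    return {(r.start, r.end, r.strand, r.frame) for r in regions}


def _linear(seq, **kw):
    return Mitogenome(id="t", sequence=seq, circular=False, **kw)


def _circular(seq, **kw):
    return Mitogenome(id="t", sequence=seq, circular=True, **kw)


def test_polyc_linear_six_regions():
    g = _linear("C" * 1200)
    regions = stop_free_regions(g, cfg=ScanConfig(circular=False))
    assert len(regions) == 6
    lengths = sorted(r.length_nt for r in regions)
    assert lengths == [1197, 1197, 1197, 1197, 1200, 1200]


def test_stop_bounded_region():
    g = _linear("TAA" + "C" * 600 + "TAG")
    regions = stop_free_regions(g, cfg=ScanConfig(circular=False,
                                                  min_len_primary=360))
    frame0 = [r for r in regions if r.frame == 0 and r.strand == "+"]
    assert len(frame0) == 1
    assert (frame0[0].start, frame0[0].end) == (3, 603)


def test_no_stop_in_any_reported_region(rng):
    for _ in range(50):
        L = int(rng.integers(600, 3000))
        seq = "".join(rng.choice(list("ACGT"), size=L))
        for circular in (False, True):
            g = Mitogenome(id="t", sequence=seq, circular=circular)
            for r in stop_free_regions(g, cfg=ScanConfig(circular=circular)):
                assert r.length_nt % 3 == 0
                assert "*" not in translate(r.sequence(g))


def test_oracle_equivalence_random_sequences(rng):
    """Scanner output equals a translate-and-split brute-force oracle."""
    for _ in range(150):
        L = int(rng.integers(600, 3000))
        gc = float(rng.uniform(0.2, 0.6))
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        seq = "".join(rng.choice(list("ACGT"), p=p, size=L))
        circular = bool(rng.integers(0, 2))
        g = Mitogenome(id="t", sequence=seq, circular=circular)
        got = _regions_as_set(
            stop_free_regions(g, cfg=ScanConfig(circular=circular)))
        want = oracle_stop_free_regions(seq, circular, 360)
        assert got == want


def test_monotonicity_in_thresholds(rng):
    seq = "".join(rng.choice(list("ACGT"), size=2400))
    g = _circular(seq)
    counts = []
    for thr in (210, 360, 600, 900):
        cfg = ScanConfig(min_len_primary=thr, min_len_secondary=210)
        counts.append(len(stop_free_regions(g, cfg=cfg)))
    assert counts == sorted(counts, reverse=True)


def test_strand_symmetry_of_scan(rng):
    seq = "".join(rng.choice(list("ACGT"), size=1500))
    g = _linear(seq)
    g_rc = _linear(revcomp(seq))
    fwd = stop_free_regions(g, cfg=ScanConfig(circular=False))
    rc = stop_free_regions(g_rc, cfg=ScanConfig(circular=False))
    n = len(seq)
    reflected = {(n - r.end, n - r.start,
                  "+" if r.strand == "-" else "-", r.frame) for r in rc}
    assert _regions_as_set(fwd) == reflected


def test_circular_region_spans_origin():
    # 600 nt stop-free run deliberately split by the origin
    body = "C" * 600
    seq = body[300:] + "TAA" + "C" * 100 + "TAG" + body[:300]
    g = _circular(seq)
    regions = stop_free_regions(g, cfg=ScanConfig())
    wrapping = [r for r in regions if r.wraps]
    assert any(r.length_nt == 600 for r in wrapping)


def test_split_by_trna_codon_trimming():
    g = _linear("C" * 600, features=[Feature("trnX", "tRNA", 300, 365)])
    region = CandidateRegion(0, 600, "+", 0, 600, ["primary_filter"])
    parts = split_by_trna([region], g)
    assert [(p.start, p.end) for p in parts] == [(0, 300), (366, 600)]
    assert [p.length_nt for p in parts] == [300, 234]
    assert all("trna_split" in p.provenance for p in parts)


def test_split_no_overlap_unchanged():
    g = _linear("C" * 600, features=[Feature("trnX", "tRNA", 590, 599)])
    region = CandidateRegion(0, 300, "+", 0, 600, [])
    parts = split_by_trna([region], g)
    assert [(p.start, p.end) for p in parts] == [(0, 300)]
    assert parts[0].provenance == []


def test_split_region_inside_trna_removed():
    g = _linear("C" * 600, features=[Feature("trnX", "tRNA", 0, 400)])
    region = CandidateRegion(100, 160, "+", 1, 600, [])
    assert split_by_trna([region], g) == []


def test_secondary_filter_thresholds():
    mk = lambda ln: CandidateRegion(0, ln, "+", 0, 5000, [])
    kept = secondary_filter([mk(300), mk(234), mk(207)], ScanConfig())
    assert [r.length_nt for r in kept] == [300, 234]
    assert secondary_filter([], ScanConfig()) == []


def test_classify_discards_annotated_overlap():
    g = _linear("C" * 2000, features=[Feature("COX1", "PCG", 100, 700)])
    inside = CandidateRegion(150, 650, "+", 0, 2000, [])
    outside = CandidateRegion(800, 1400, "+", 2, 2000, [])
    feats = classify_orfans([inside, outside], g)
    assert [f.name for f in feats] == ["ORFan-600"]
    assert feats[0].start == 800


def test_classify_keeps_longest_per_cluster():
    g = _linear("C" * 2000)
    a = CandidateRegion(100, 644, "+", 0, 2000, [])
    b = CandidateRegion(200, 620, "-", 1, 2000, [])
    feats = classify_orfans([a, b], g)
    assert len(feats) == 1
    assert feats[0].name == "ORFan-544"


def test_control_region_requires_pcg_annotation():
    g = _linear("AT" * 300)
    with pytest.raises(ValueError, match="PCG"):
        control_region_candidates(g)


def test_control_region_heuristic():
    # GC-rich PCGs separate an AT-rich stop-dense gap (CR-like) from a
    # stop-free gap (not CR-like)
    pcg = "GGCGCTGGA" * 40  # no TAA/TAG in any frame of this repeat
    at_gap = "TAATTAATTAATTAA" * 20  # stops in all six frames, GC 0
    cc_gap = "C" * 300  # no stops anywhere -> not CR-like
    seq = pcg + at_gap + pcg + cc_gap
    g = _linear(seq, features=[
        Feature("pcg1", "PCG", 0, len(pcg)),
        Feature("pcg2", "PCG", len(pcg) + len(at_gap),
                2 * len(pcg) + len(at_gap))])
    cands = control_region_candidates(g)
    assert len(cands) == 1
    assert (cands[0].start, cands[0].end) == (len(pcg), len(pcg) + len(at_gap))


def test_full_pipeline_recovers_simulated_orfans(sim_genome):
    genome, truth = sim_genome
    found = find_orfans(genome)
    got = {(f.start, f.end, f.strand) for f in found}
    want = {(f.start, f.end, f.strand) for f in truth.orfans}
    assert got == want


def test_cr_candidate_matches_simulated_truth(sim_genome):
    genome, truth = sim_genome
    cands = control_region_candidates(genome)
    assert [(c.start, c.end) for c in cands] == [(truth.cr.start,
                                                  truth.cr.end)]


def test_genome_shorter_than_codon_rejected():
    with pytest.raises(ValueError):
        stop_free_regions(_linear("AC"), cfg=ScanConfig(circular=False))
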