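"""The synthetic mitogenome and codon-evolution generators."""

import numpy as np
import pytest

from mitorfan.genetic_code import TABLE5, revcomp, translate
from mitorfan.synthetic_data import (EvolConfig, SimConfig,
                                     evolve_codon_alignment,
                                     random_coding_sequence, simulate_depth,
                                     simulate_mitogenome)


def test_seeded_determinism():
    g1, t1 = simulate_mitogenome(SimConfig(seed=5))
    g2, t2 = simulate_mitogenome(SimConfig(seed=5))
    assert g1.sequence == g2.sequence
    assert [(f.name, f.start, f.end) for f in t1.orfans] == \
        [(f.name, f.start, f.end) for f in t2.orfans]
    g3, _ = simulate_mitogenome(SimConfig(seed=6))
    assert g3.sequence != g1.sequence


def test_structure_counts(sim_genome):
    genome, truth = sim_genome
    assert len(genome.features_of("PCG")) == 13
    assert len(genome.features_of("tRNA")) == 23  # 22 + duplicated trnM
    names = [f.name for f in genome.features_of("tRNA")]
    assert names.count("trnM") == 2
    assert len(genome.features_of("rRNA")) == 2
    assert len(truth.orfans) == 3
    assert truth.cr is not None


def test_coding_features_are_stop_free(sim_genome):
    genome, truth = sim_genome
    for f in truth.orfans:
        prot = translate(genome.feature_seq(f))
        assert "*" not in prot
    for f in genome.features_of("PCG"):
        prot = translate(genome.feature_seq(f))
        assert prot.count("*") == 1 and prot.endswith("*")


def test_orfans_flanked_by_inframe_stops(sim_genome):
    genome, truth = sim_genome
    for f in truth.orfans:
        before = genome.sequence[f.start - 3:f.start]
        after = genome.sequence[f.end:f.end + 3]
        assert TABLE5.is_stop(before)
        assert TABLE5.is_stop(after)


def test_cr_has_stops_in_all_six_frames(sim_genome):
    genome, truth = sim_genome
    seq = genome.sequence[truth.cr.start:truth.cr.end]
    for work in (seq, revcomp(seq)):
        for frame in range(3):
            assert any(TABLE5.is_stop(work[p:p + 3])
                       for p in range(frame, len(work) - 2, 3))


def test_cr_gc_below_all_pcgs(sim_genome):
    genome, truth = sim_genome

    def gc(s):
        return (s.count("G") + s.count("C")) / len(s)

    cr_gc = gc(genome.sequence[truth.cr.start:truth.cr.end])
    pcg_gcs = [gc(genome.feature_seq(f)) for f in genome.features_of("PCG")]
    assert cr_gc < min(pcg_gcs)


def test_features_non_overlapping(sim_genome):
    genome, truth = sim_genome
    feats = sorted(truth.all_features, key=lambda f: f.start)
    for a, b in zip(feats, feats[1:]):
        assert a.end <= b.start


def test_genome_length_padding():
    g, _ = simulate_mitogenome(SimConfig(seed=3, genome_length=21000))
    assert len(g) == 21000
    with pytest.raises(ValueError, match="budget"):
        simulate_mitogenome(SimConfig(seed=3, genome_length=5000))


def test_orfan_lengths_must_be_codon_multiples():
    with pytest.raises(ValueError):
        SimConfig(orfan_specs=((400, 2),))


# -- codon evolution --------------------------------------------------------

def test_omega_zero_preserves_protein(uniform_weights):
    anc = random_coding_sequence(100, uniform_weights,
                                 np.random.default_rng(0), start_codon=None)
    aln = evolve_codon_alignment(anc, EvolConfig(n_taxa=4, omega=0.0,
                                                 branch_length=3.0, seed=1))
    anc_prot = translate(anc)
    assert any(row != anc for row in aln.rows)  # synonymous changes happened
    for row in aln.rows:
        assert translate(row) == anc_prot


def test_zero_branch_length_identical_rows(uniform_weights):
    anc = random_coding_sequence(80, uniform_weights,
                                 np.random.default_rng(1), start_codon=None)
    aln = evolve_codon_alignment(anc, EvolConfig(n_taxa=3, omega=0.5,
                                                 branch_length=0.0, seed=2))
    assert all(row == anc for row in aln.rows)


def test_evolved_rows_stay_stop_free(uniform_weights):
    anc = random_coding_sequence(150, uniform_weights,
                                 np.random.default_rng(2), start_codon=None)
    aln = evolve_codon_alignment(anc, EvolConfig(n_taxa=5, omega=2.0,
                                                 branch_length=1.5, seed=3))
    for row in aln.rows:
        assert "*" not in translate(row)
        assert len(row) == len(anc)


def test_negative_omega_rejected():
    with pytest.raises(ValueError):
        EvolConfig(omega=-0.1)


def test_evolution_seed_determinism(uniform_weights):
    anc = random_coding_sequence(60, uniform_weights,
                                 np.random.default_rng(3), start_codon=None)
    a = evolve_codon_alignment(anc, EvolConfig(seed=9))
    b = evolve_codon_alignment(anc, EvolConfig(seed=9))
    assert a.rows == b.rows


def test_dnds_monotone_in_omega(uniform_weights):
    """Estimated pN/pS preserves the ranking of the simulated omegas."""
    from mitorfan.codon_evol import dn_ds
    omegas = [0.1, 0.3, 0.5, 1.0]
    estimates = []
    for k, omega in enumerate(omegas):
        vals = []
        for rep in range(5):
            anc = random_coding_sequence(
                300, uniform_weights,
                np.random.default_rng(1000 + 10 * k + rep), start_codon=None)
            aln = evolve_codon_alignment(
                anc, EvolConfig(n_taxa=5, omega=omega, seed=2000 + 10 * k + rep))
            _, _, dnds = dn_ds(aln)
            vals.append(dnds)
        estimates.append(np.mean(vals))
    assert estimates == sorted(estimates)


# -- depth simulation -------------------------------------------------------

def test_depth_all_zero_levels(sim_genome):
    genome, truth = sim_genome
    levels = {f.name: 0.0 for f in truth.all_features}
    track = simulate_depth(genome, levels, features=truth.all_features,
                           background=0.0, seed=0)
    assert track.depth.sum() == 0


def test_depth_seeded_determinism(sim_genome):
    genome, truth = sim_genome
    levels = {f.name: 12.0 for f in truth.all_features}
    a = simulate_depth(genome, levels, features=truth.all_features, seed=4)
    b = simulate_depth(genome, levels, features=truth.all_features, seed=4)
    assert np.array_equal(a.depth, b.depth)


def test_negative_levels_rejected(sim_genome):
    genome, truth = sim_genome
    with pytest.raises(ValueError):
        simulate_depth(genome, {"cox1": -1.0})
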