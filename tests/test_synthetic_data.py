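"""Generators: seed determinism, planted ground truth round trips, and
signal models at zero noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conpromo.genome_annotation import classify_spacer
from conpromo.promoter_scan import (
    CONSENSUS_10,
    CONSENSUS_35,
    hexamer_match,
    scan_sequence,
)
from conpromo.synthetic_data import (
    GenomeSequence,
    SyntheticConfig,
    generate_genome,
    plant_gene_layout,
    plant_promoter,
    simulate_array_signal,
    simulate_time_course,
)

# ------------------------------------------------------------------- genomes


def test_generate_genome_is_seed_deterministic():
    a = generate_genome(1000, 0.5, 1)
    b = generate_genome(1000, 0.5, 1)
    assert a.seq == b.seq and len(a) == 1000
    assert generate_genome(1000, 0.5, 2).seq != a.seq


def test_generate_genome_degenerate_gc_gives_only_at():
    g = generate_genome(1000, 0.0, 2)
    assert set(g.seq) <= {"A", "T"}


def test_generate_genome_gc_within_binomial_bound():
    n, p = 100_000, 0.5
    g = generate_genome(n, p, 3)
    gc = sum(1 for b in g.seq if b in "GC") / n
    sd = np.sqrt(p * (1 - p) / n)
    assert abs(gc - p) < 3 * sd


def test_generate_genome_rejects_short():
    with pytest.raises(ValueError):
        generate_genome(10, 0.5, 1)


def test_genome_sequence_validates_alphabet_and_length():
    with pytest.raises(ValueError):
        GenomeSequence("x", "ACGTX")
    with pytest.raises(ValueError):
        GenomeSequence("x", "")


def test_circular_subseq_wraps_origin():
    g = GenomeSequence("x", "AACCGGTT", circular=True)
    assert g.subseq(6, 10) == "TTAA"
    assert g.subseq(6, 10, "-") == "TTAA"[::-1].translate(str.maketrans("AT", "TA"))


# -------------------------------------------------------------------- layout


def test_layout_type_a_is_divergent_pair():
    g = generate_genome(2000, 0.5, 1)
    ann = plant_gene_layout(g, [("A", 500)])
    left, right = ann.genes
    assert (left.strand, right.strand) == ("-", "+")
    assert right.start - left.end == 500
    assert ann.planted_spacers == [(left.end, right.start, "A")]


def test_layout_type_c_points_into_gap():
    g = generate_genome(1000, 0.5, 1)
    ann = plant_gene_layout(g, [("C", 200)])
    left, right = ann.genes
    assert (left.strand, right.strand) == ("+", "-")


def test_layout_empty_is_empty():
    g = generate_genome(1000, 0.5, 1)
    ann = plant_gene_layout(g, [])
    assert ann.genes == [] and ann.planted_spacers == []


def test_layout_overflow_rejected():
    g = generate_genome(1000, 0.5, 1)
    with pytest.raises(ValueError):
        plant_gene_layout(g, [("A", 5000)])


def test_layout_classification_round_trip():
    """Every planted spacer class is recovered from the flanking strands."""
    g = generate_genome(20_000, 0.5, 7)
    layout = [("A", 100), ("B", 150), ("C", 120), ("B", 90), ("A", 60)]
    ann = plant_gene_layout(g, layout)
    for (sp_start, sp_end, code), (left, right) in zip(
        ann.planted_spacers, zip(ann.genes[::2], ann.genes[1::2])
    ):
        assert classify_spacer(left.strand, right.strand) == code
        assert (left.end, right.start) == (sp_start, sp_end)


# ----------------------------------------------------------------- promoters


def test_plant_perfect_promoter_writes_consensus():
    g = generate_genome(1000, 0.5, 1)
    g2, truth = plant_promoter(g, 10, "+", 6, 6, 17, 4)
    assert g2.seq[10:16] == CONSENSUS_35
    assert g2.seq[33:39] == CONSENSUS_10
    assert truth.pos35 == 10
    assert len(g2) == len(g)


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    m35=st.integers(0, 6),
    m10=st.integers(0, 6),
    spacer=st.integers(15, 19),
    strand=st.sampled_from("+-"),
    seed=st.integers(0, 2**16),
)
def test_plant_recount_round_trip(m35, m10, spacer, strand, seed):
    """Recounting the written boxes always returns the planted match counts."""
    g = generate_genome(400, 0.5, 11)
    g2, truth = plant_promoter(g, 50, strand, m35, m10, spacer, seed)
    cassette = g2.subseq(50, 50 + 12 + spacer, strand)
    assert hexamer_match(cassette[:6], CONSENSUS_35) == m35
    assert hexamer_match(cassette[-6:], CONSENSUS_10) == m10
    assert (truth.m35, truth.m10, truth.spacer_len) == (m35, m10, spacer)


def test_plant_minus_strand_recovered_by_scanner():
    g = generate_genome(600, 0.5, 5)
    g2, truth = plant_promoter(g, 100, "-", 6, 6, 17, 8)
    matches = [
        h
        for h in scan_sequence(g2.seq)
        if h.strand == "-" and h.pos35 == truth.pos35 and h.total == 15
    ]
    assert len(matches) == 1


def test_plant_rejects_overflow_and_bad_counts():
    g = generate_genome(100, 0.5, 1)
    with pytest.raises(ValueError):
        plant_promoter(g, 95, "+", 6, 6, 17, 1)
    with pytest.raises(ValueError):
        plant_promoter(g, 10, "+", 7, 6, 17, 1)


# -------------------------------------------------------------- array signal


def test_array_signal_no_peaks_no_noise_ratio_one():
    cfg = SyntheticConfig(genome_length=5000, noise_sd=0.0, seed=1)
    t = simulate_array_signal(5000, cfg, [])
    assert np.allclose(t["cy5"] / t["cy3"], 1.0)
    assert list(t["probe_start"][:3]) == [0, 105, 210]


def test_array_signal_single_peak_kernel_arithmetic():
    cfg = SyntheticConfig(genome_length=5000, noise_sd=0.0, seed=1)
    t = simulate_array_signal(5000, cfg, [(2100, 99.0)])  # 2100 = 20 * 105
    ratio = (t["cy5"] / t["cy3"]).to_numpy()
    assert ratio.max() == pytest.approx(100.0)
    assert int(t["probe_start"][np.argmax(ratio)]) == 2100
    # half-width 150 bp > 105 bp spacing: neighbours are also elevated
    assert np.sum(ratio > 2.0) >= 2
    elevated = np.flatnonzero(ratio > 2.0)
    assert np.all(np.diff(elevated) == 1)


def test_array_signal_two_separated_peaks_disjoint_runs():
    cfg = SyntheticConfig(genome_length=5000, noise_sd=0.0, seed=1)
    t = simulate_array_signal(5000, cfg, [(1050, 50.0), (1450, 50.0)])
    ratio = (t["cy5"] / t["cy3"]).to_numpy()
    elevated = np.flatnonzero(ratio > 1.5)
    assert np.any(np.diff(elevated) > 1)  # gap between the two runs


def test_array_signal_rejects_out_of_range_peak():
    cfg = SyntheticConfig(genome_length=1000, seed=1)
    with pytest.raises(ValueError):
        simulate_array_signal(1000, cfg, [(5000, 10.0)])


def test_array_signal_seed_determinism():
    cfg = SyntheticConfig(genome_length=3000, noise_sd=0.2, seed=42)
    a = simulate_array_signal(3000, cfg, [(500, 20.0)])
    b = simulate_array_signal(3000, cfg, [(500, 20.0)])
    assert a.equals(b)


# -------------------------------------------------------------- time courses


def test_time_course_zero_time_and_plateau():
    t0 = simulate_time_course(100, 0.5, [0.0], 0.0, 1)
    assert t0["signal"].iloc[0] == 0.0
    plateau = simulate_time_course(100, 0.5, [1e6], 0.0, 1)
    assert plateau["signal"].iloc[0] == pytest.approx(100.0)


def test_time_course_half_life():
    t = simulate_time_course(100, 0.5, [np.log(2) / 0.5], 0.0, 1)
    assert t["signal"].iloc[0] == pytest.approx(50.0, rel=1e-9)


def test_time_course_rejects_nonpositive_parameters():
    with pytest.raises(ValueError):
        simulate_time_course(0, 0.5, [1.0])
    with pytest.raises(ValueError):
        simulate_time_course(100, -1, [1.0])


def test_synthetic_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(probe_interval=0)
    with pytest.raises(ValueError):
        SyntheticConfig(gc_fraction=1.0)
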