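"""Read generation: budgets, placement, insert law, errors, FASTQ output."""

import gzip

import numpy as np
import pytest
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from hypothesis import given, settings, strategies as st

from linkedsim import (
    DiploidGenome,
    QualityModel,
    ReadParams,
    apply_errors,
    emit_fastq,
    generate_reference,
    read_budget,
    simulate_pe_reads,
    simulate_se_reads,
)
from linkedsim.fragments import Fragment
from linkedsim.reads import _inject_errors, calibrate_error_scale, reverse_complement


@pytest.fixture(scope="module")
def frag_genome():
    ref = generate_reference(120_000, seed=55)
    genome = DiploidGenome(hap1={"c": ref}, hap2={"c": ref})
    frag = Fragment(id=0, hap=1, contig="c", start=10_000, end=60_000)  # 50 kb
    return genome, frag


@pytest.mark.parametrize(
    "cr, v, rl, expected",
    [(0.1, 35_000_000, 100, 35_000), (0.1, 35_000_000, 1000, 3_500), (0, 1_000, 100, 0)],
)
def test_read_budget(cr, v, rl, expected):
    assert read_budget(cr, v, rl) == expected


def test_read_budget_rejects_zero_rl():
    with pytest.raises(ValueError):
        read_budget(0.1, 1000, 0)


def test_pe_pair_count_from_budget(frag_genome):
    """50 kb fragment at CR=0.5, RL=100: 250 reads = 125 pairs."""
    genome, frag = frag_genome
    params = ReadParams(mode="PE", rl=100, cr=0.5, mu_is=600, seed=1)
    assert len(simulate_pe_reads(frag, genome, params)) == 125


def test_pe_no_noise_reads_match_reference(frag_genome):
    """With error_rate=0 every mate equals the exact haplotype substring at
    its truth coordinates (mate 2 reverse-complemented), FR orientation."""
    genome, frag = frag_genome
    params = ReadParams(mode="PE", rl=100, cr=0.5, mu_is=600, sigma_is=0, error_rate=0, seed=2)
    hapseq = genome.hap1["c"]
    for pair in simulate_pe_reads(frag, genome, params):
        m1, m2 = pair.mate1, pair.mate2
        assert (m1.strand, m2.strand) == ("+", "-")
        assert m1.sequence == hapseq[m1.ref_start : m1.ref_end]
        assert m2.sequence == reverse_complement(hapseq[m2.ref_start : m2.ref_end])
        assert frag.start <= m1.ref_start < m2.ref_end <= frag.end
        assert pair.insert >= 2 * params.rl


def test_pe_insert_clamped_to_fragment(frag_genome):
    """A fragment exactly mu_IS long forces every pair to span it fully."""
    genome, _ = frag_genome
    frag = Fragment(id=1, hap=1, contig="c", start=20_000, end=20_600)
    params = ReadParams(mode="PE", rl=100, cr=4.0, mu_is=600, sigma_is=0, error_rate=0, seed=3)
    pairs = simulate_pe_reads(frag, genome, params)
    assert pairs
    for pair in pairs:
        assert pair.mate1.ref_start == frag.start
        assert pair.mate2.ref_end == frag.end
        assert pair.insert == 600


def test_pe_insert_mean_recovers_mu_is(frag_genome):
    """Empirical insert mean within 1% of 600 bp over >= 10^4 pairs."""
    genome, frag = frag_genome
    params = ReadParams(mode="PE", rl=100, cr=40.0, mu_is=600, seed=4)
    inserts = [p.insert for p in simulate_pe_reads(frag, genome, params)]
    assert len(inserts) >= 10_000
    assert np.mean(inserts) == pytest.approx(600, rel=0.01)


def test_pe_short_fragment_yields_no_pairs(frag_genome):
    genome, _ = frag_genome
    frag = Fragment(id=2, hap=1, contig="c", start=0, end=150)
    params = ReadParams(mode="PE", rl=100, cr=1.0, mu_is=600, seed=5)
    assert simulate_pe_reads(frag, genome, params) == []


def test_se_read_count_and_bounds(frag_genome):
    """50 kb fragment at CR=0.5, RL=500: 50 single-end reads, all inside."""
    genome, frag = frag_genome
    params = ReadParams(mode="SE", rl=500, cr=0.5, seed=6)
    reads = simulate_se_reads(frag, genome, params)
    assert len(reads) == 50
    for r in reads:
        assert frag.start <= r.ref_start < r.ref_end <= frag.end
        assert r.ref_end - r.ref_start == 500


def test_se_fragment_shorter_than_read_skipped(frag_genome):
    genome, _ = frag_genome
    frag = Fragment(id=3, hap=1, contig="c", start=0, end=999)
    params = ReadParams(mode="SE", rl=1000, cr=1.0, seed=7)
    assert simulate_se_reads(frag, genome, params) == []


def test_se_strand_balance(frag_genome):
    """Forward fraction is 1/2 within 3 sigma binomial."""
    genome, frag = frag_genome
    params = ReadParams(mode="SE", rl=100, cr=40.0, seed=8)
    reads = simulate_se_reads(frag, genome, params)
    n = len(reads)
    assert n >= 10_000
    fwd = sum(r.strand == "+" for r in reads)
    assert abs(fwd - n / 2) <= 3 * np.sqrt(n * 0.25)


def test_se_no_noise_matches_reference(frag_genome):
    genome, frag = frag_genome
    params = ReadParams(mode="SE", rl=500, cr=0.5, error_rate=0, seed=9)
    hapseq = genome.hap1["c"]
    for r in simulate_se_reads(frag, genome, params):
        expected = hapseq[r.ref_start : r.ref_end]
        assert r.sequence == (reverse_complement(expected) if r.strand == "-" else expected)


def test_simulation_deterministic(frag_genome):
    genome, frag = frag_genome
    params = ReadParams(mode="PE", rl=100, cr=0.5, mu_is=600, seed=10)
    a = simulate_pe_reads(frag, genome, params)
    b = simulate_pe_reads(frag, genome, params)
    assert [(p.mate1.sequence, p.mate1.qualities, p.mate2.sequence) for p in a] == [
        (p.mate1.sequence, p.mate1.qualities, p.mate2.sequence) for p in b
    ]


def test_apply_errors_zero_rate_is_identity():
    seq = generate_reference(5_000, seed=60)
    assert apply_errors(seq, [30] * 5_000, 0.0, seed=1) == seq


def test_apply_errors_binomial_rate():
    """At a calibrated 1% over 10^6 bases, the substitution count sits within
    3 sigma of 10,000 (binomial oracle)."""
    seq = generate_reference(1_000_000, seed=61)
    out = apply_errors(seq, [30] * 1_000_000, 0.01, seed=2)
    mismatches = sum(a != b for a, b in zip(seq, out))
    assert abs(mismatches - 10_000) <= 3 * np.sqrt(1_000_000 * 0.01 * 0.99)


def test_apply_errors_never_touches_n():
    seq = "N" * 1000
    assert apply_errors(seq, [2] * 1000, 0.5, seed=3) == seq


def test_error_calibration_honours_rate_under_any_profile():
    """The calibrated scale makes E[p] equal the configured rate for both a
    flat and a declining quality profile."""
    for qmodel in (QualityModel.flat(100, q=35, sd=2), QualityModel.default(100)):
        scale = calibrate_error_scale(qmodel, 0.01)
        qs = np.arange(2, 42)
        p = qmodel.quality_pmf() @ (10.0 ** (-qs / 10.0))
        assert float(np.mean(scale * p)) == pytest.approx(0.01, rel=1e-9)


def test_per_cycle_error_rates_follow_quality_profile():
    """Flat profile: first and last cycle rates agree within sampling noise;
    declining profile: last cycle is clearly noisier than the first."""
    rng = np.random.default_rng(62)
    n, rl = 30_000, 100
    base = np.full((n, rl), ord("A"), dtype=np.uint8)

    flat = QualityModel.flat(rl, q=30, sd=0)
    mat = base.copy()
    quals = flat.sample(rng, n)
    _inject_errors(mat, quals, calibrate_error_scale(flat, 0.02), rng)
    rates = (mat != ord("A")).mean(axis=0)
    assert abs(rates[0] - rates[-1]) < 6 * np.sqrt(0.02 * 0.98 / n)

    declining = QualityModel.default(rl)
    mat = base.copy()
    quals = declining.sample(rng, n)
    _inject_errors(mat, quals, calibrate_error_scale(declining, 0.02), rng)
    rates = (mat != ord("A")).mean(axis=0)
    assert rates[-1] > 2 * rates[0]


@given(st.text(alphabet="ACGTN", min_size=1, max_size=200), st.integers(0, 2**31 - 1))
@settings(max_examples=50, derandomize=True)
def test_apply_errors_preserves_length_and_alphabet(seq, seed):
    out = apply_errors(seq, [20] * len(seq), 0.2, seed=seed)
    assert len(out) == len(seq)
    assert set(out) <= set("ACGTN")
    assert all(a == b for a, b in zip(seq, out) if a == "N")


def test_quality_model_table_round_trip(tmp_path):
    path = tmp_path / "profile.tsv"
    path.write_text("cycle\tmean_q\tsd_q\n" + "".join(f"{c}\t{30 + c % 5}\t1.5\n" for c in range(1, 51)))
    qm = QualityModel.from_table(path)
    assert qm.rl == 50
    assert qm.mean_q[0] == 31


def test_emit_fastq_pe_structure_and_round_trip(tmp_path, frag_genome):
    """Two pairs produce two 8-line gzip files with matched names; parsing
    recovers sequences and qualities byte-identically."""
    genome, frag = frag_genome
    params = ReadParams(mode="PE", rl=100, cr=0.5, mu_is=600, seed=11)
    pairs = simulate_pe_reads(frag, genome, params, barcode_tag="3_7_11")[:2]
    out = emit_fastq(pairs, tmp_path / "lib", params)
    assert out["n_reads"] == 4
    r1, r2 = out["fastq"]
    with gzip.open(r1, "rt") as fh:
        lines1 = fh.read().splitlines()
    with gzip.open(r2, "rt") as fh:
        lines2 = fh.read().splitlines()
    assert len(lines1) == len(lines2) == 8
    for l1, l2 in zip(lines1[::4], lines2[::4]):
        assert l1.endswith("#3_7_11/1") and l2.endswith("#3_7_11/2")
        assert l1[:-2] == l2[:-2]
    with gzip.open(r1, "rt") as fh:
        parsed = list(FastqGeneralIterator(fh))
    assert [(p.mate1.sequence, p.mate1.qualities) for p in pairs] == [
        (seq, qual) for _name, seq, qual in parsed
    ]


def test_emit_fastq_unbarcoded_uses_null_tag(tmp_path, frag_genome):
    genome, frag = frag_genome
    params = ReadParams(mode="SE", rl=100, cr=0.1, barcode_on=False, seed=12)
    reads = simulate_se_reads(frag, genome, params)
    out = emit_fastq(reads, tmp_path / "ngs", params)
    with gzip.open(out["fastq"][0], "rt") as fh:
        for name, _seq, _qual in FastqGeneralIterator(fh):
            assert name.endswith("#0_0_0")
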