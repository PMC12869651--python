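"""Long-fragment simulation: volume targeting, length law, placement."""

import numpy as np
import pytest
from scipy import stats

from linkedsim import (
    DiploidGenome,
    FragmentPlan,
    expected_barcode_count,
    generate_reference,
    simulate_fragments,
    total_dna_volume,
)
from linkedsim.errors import UnsatisfiablePlanError
from linkedsim.fragments import (
    achieved_physical_coverage,
    read_fragment_manifest,
    write_fragment_manifest,
)


@pytest.mark.parametrize(
    "cf, L, expected",
    [(35, 1_000_000, 35_000_000), (0, 1_000_000, 0), (70, 1_000_000, 70_000_000)],
)
def test_total_dna_volume(cf, L, expected):
    assert total_dna_volume(cf, L) == expected


def test_total_dna_volume_rejects_negative():
    with pytest.raises(ValueError):
        total_dna_volume(-1, 10)


@pytest.mark.parametrize(
    "cf, g, mu, expected",
    [
        (100, 1_000_000, 50_000, 2_000),
        (350, 1_000_000, 50_000, 7_000),
        (1, 10_000, 50_000, 1),  # ceil(0.2)
    ],
)
def test_expected_barcode_count(cf, g, mu, expected):
    assert expected_barcode_count(cf, g, mu) == expected


def test_expected_barcode_count_rejects_zero_mu():
    with pytest.raises(ValueError):
        expected_barcode_count(100, 1_000_000, 0)


@pytest.fixture(scope="module")
def genome_1mb():
    ref = generate_reference(1_000_000, seed=41)
    return DiploidGenome(hap1={"c": ref}, hap2={"c": ref})


def test_volume_conservation_and_count(genome_1mb):
    """Per haplotype, summed fragment bases land in
    [(CF/2) L_h, (CF/2) L_h + longest fragment) and the count is near
    (CF/2) L_h / mu_FL."""
    plan = FragmentPlan(cf=35, mu_fl=50_000, seed=5)
    frags = simulate_fragments(genome_1mb, plan)
    for hap in (1, 2):
        sub = [f for f in frags if f.hap == hap]
        total = sum(f.length for f in sub)
        target = 0.5 * 35 * 1_000_000
        assert target <= total < target + max(f.length for f in sub)
        assert len(sub) == pytest.approx(350, rel=0.20)


def test_coverage_recovery_multiple_seeds(genome_1mb):
    """Achieved CF/2 recovers the target within 5% across seeds."""
    for seed in range(6):
        frags = simulate_fragments(genome_1mb, FragmentPlan(cf=35, mu_fl=50_000, seed=seed))
        cov = achieved_physical_coverage(frags, genome_1mb)
        assert cov[1] == pytest.approx(17.5, rel=0.05)
        assert cov[2] == pytest.approx(17.5, rel=0.05)


def test_fragment_intervals_and_minimum_length(genome_1mb):
    plan = FragmentPlan(cf=10, mu_fl=20_000, min_fl=1500, seed=9)
    frags = simulate_fragments(genome_1mb, plan)
    for f in frags:
        assert 0 <= f.start < f.end <= 1_000_000
        assert f.length >= 1500


def test_output_sorted_and_ids_serial(genome_1mb):
    frags = simulate_fragments(genome_1mb, FragmentPlan(cf=10, mu_fl=50_000, seed=2))
    assert [f.id for f in frags] == list(range(len(frags)))
    keys = [(f.hap, f.start) for f in frags]
    assert keys == sorted(keys)


def test_determinism_and_seed_sensitivity(genome_1mb):
    plan = FragmentPlan(cf=5, mu_fl=50_000, seed=7)
    a = simulate_fragments(genome_1mb, plan)
    b = simulate_fragments(genome_1mb, plan)
    assert [(f.hap, f.contig, f.start, f.end) for f in a] == [
        (f.hap, f.contig, f.start, f.end) for f in b
    ]
    c = simulate_fragments(genome_1mb, FragmentPlan(cf=5, mu_fl=50_000, seed=8))
    assert [(f.start, f.end) for f in a] != [(f.start, f.end) for f in c]


def test_haplotype_streams_independent(genome_1mb):
    """Haplotype 1's fragments do not move when haplotype 2's assembly
    changes (per-haplotype child RNG streams)."""
    other = DiploidGenome(
        hap1=dict(genome_1mb.hap1),
        hap2={"alt": generate_reference(500_000, seed=77)},
    )
    plan = FragmentPlan(cf=5, mu_fl=50_000, seed=3)
    a = [f for f in simulate_fragments(genome_1mb, plan) if f.hap == 1]
    b = [f for f in simulate_fragments(other, plan) if f.hap == 1]
    assert [(f.start, f.end) for f in a] == [(f.start, f.end) for f in b]


def test_cf_zero_yields_no_fragments(genome_1mb):
    assert simulate_fragments(genome_1mb, FragmentPlan(cf=0, mu_fl=50_000, seed=1)) == []


def test_unsatisfiable_plan_raises():
    tiny = DiploidGenome(hap1={"c": "ACGT" * 50}, hap2={"c": "ACGT" * 50})
    with pytest.raises(UnsatisfiablePlanError, match="min_FL"):
        simulate_fragments(tiny, FragmentPlan(cf=5, mu_fl=1000, min_fl=1000, seed=0))


def test_high_n_fragments_rejected():
    """An all-N region contributes no fragments (N fraction cap), yet the
    plan still completes using the clean contig."""
    ref = generate_reference(400_000, seed=13)
    n_block = "N" * 200_000
    genome = DiploidGenome(
        hap1={"c": ref[:200_000] + n_block}, hap2={"c": ref[:200_000] + n_block}
    )
    frags = simulate_fragments(genome, FragmentPlan(cf=4, mu_fl=20_000, seed=4))
    for f in frags:
        seq = genome.haplotype(f.hap)[f.contig][f.start : f.end]
        assert seq.count("N") <= 0.5 * f.length


def test_start_positions_uniform(genome_1mb):
    """Chi-square over 20 equal bins of start positions does not reject at
    alpha=0.01 in >=95% of seeds."""
    passes = 0
    n_seeds = 40
    for seed in range(n_seeds):
        frags = simulate_fragments(
            genome_1mb, FragmentPlan(cf=20, mu_fl=50_000, seed=1000 + seed)
        )
        starts = np.array([f.start for f in frags])
        counts, _ = np.histogram(starts, bins=20, range=(0, 1_000_000))
        _, p = stats.chisquare(counts)
        passes += p > 0.01
    assert passes >= 0.95 * n_seeds


def test_length_law_truncated_exponential(flat_diploid_10mb):
    """Fragment lengths match an independent truncated-exponential oracle
    (same n, same rounding rule) by two-sample KS at alpha=0.01."""
    plan = FragmentPlan(cf=4, mu_fl=50_000, seed=21)
    lengths = np.array([f.length for f in simulate_fragments(flat_diploid_10mb, plan)])
    rng = np.random.default_rng(99)
    oracle = []
    while len(oracle) < lengths.size:
        draw = np.rint(rng.exponential(50_000, lengths.size)).astype(int)
        oracle.extend(draw[draw >= plan.min_fl].tolist())
    oracle = np.array(oracle[: lengths.size])
    assert stats.ks_2samp(lengths, oracle).pvalue > 0.01
    assert lengths.mean() == pytest.approx(50_000, rel=0.05)


def test_manifest_round_trip(tmp_path, genome_1mb):
    frags = simulate_fragments(genome_1mb, FragmentPlan(cf=2, mu_fl=50_000, seed=6))
    path = tmp_path / "frags.tsv"
    write_fragment_manifest(frags, path)
    rows = read_fragment_manifest(path)
    assert len(rows) == len(frags)
    for f, r in zip(frags, rows):
        assert (r["fragment_id"], r["hap"], r["contig"], r["start"], r["end"]) == (
            f.id, f.hap, f.contig, f.start, f.end,
        )
        assert r["length"] == f.length
        assert r["barcode"] is None
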