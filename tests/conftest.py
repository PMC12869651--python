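"""Shared fixtures: synthetic genomes and simulated libraries.

Heavy artefacts (simulated libraries) are session-scoped so the many tests
that inspect them pay the simulation cost once.
"""

import pytest

from linkedsim import (
    DiploidGenome,
    build_default_whitelist,
    generate_reference,
    make_config,
    simulate_library,
    synthetic_diploid,
)
from linkedsim.qc import qc_from_manifests


@pytest.fixture(scope="session")
def small_diploid():
    """~200 kb synthetic diploid with SNPs and small indels."""
    genome, variants, reference = synthetic_diploid(
        length=200_000, snp_rate=0.001, indel_rate=0.0001, seed=101
    )
    return genome, variants, reference


@pytest.fixture(scope="session")
def snp_only_diploid():
    """SNP-only diploid: haplotype coordinates equal reference coordinates."""
    genome, variants, reference = synthetic_diploid(
        length=200_000, snp_rate=0.001, indel_rate=0.0, seed=202
    )
    return genome, variants, reference


@pytest.fixture(scope="session")
def flat_diploid_10mb():
    """10 Mb-per-haplotype diploid (identical haplotypes, no variants): large
    enough that contig-end truncation touches <1% of fragments."""
    reference = generate_reference(10_000_000, seed=303)
    return DiploidGenome(hap1={"big1": reference}, hap2={"big1": reference})


@pytest.fixture(scope="session")
def default_whitelist():
    return build_default_whitelist()


@pytest.fixture(scope="session")
def stlfr_run(small_diploid, default_whitelist, tmp_path_factory):
    """One PE100_stLFR library at CF=35, CR=0.5, mu_FL=50 kb with its QC."""
    genome, _variants, _reference = small_diploid
    config = make_config("PE100_stLFR", cf=35.0, cr=0.5, mu_fl=50_000.0, seed=11)
    prefix = tmp_path_factory.mktemp("stlfr_run") / "lib"
    summary = simulate_library(genome, config, prefix, whitelist=default_whitelist)
    report = qc_from_manifests(
        summary["fragment_manifest"], summary["truth"], summary["fastq"],
        genome, config,
    )
    return {"genome": genome, "config": config, "summary": summary, "report": report}


@pytest.fixture(scope="session")
def noerror_snp_run(snp_only_diploid, default_whitelist, tmp_path_factory):
    """Zero-error PE library on the SNP-only diploid (haplotype fidelity)."""
    genome, variants, reference = snp_only_diploid
    config = make_config(
        "PE100_stLFR", cf=35.0, cr=0.5, mu_fl=50_000.0, error_rate=0.0, seed=12
    )
    prefix = tmp_path_factory.mktemp("noerror_run") / "lib"
    summary = simulate_library(genome, config, prefix, whitelist=default_whitelist)
    return {
        "genome": genome,
        "variants": variants,
        "reference": reference,
        "config": config,
        "summary": summary,
    }
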