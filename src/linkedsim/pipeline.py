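"""End-to-end library simulation: fragments -> barcodes -> reads -> FASTQ.

One call takes a diploid genome and a :class:`~linkedsim.presets.SimulationConfig`
and writes the library artefacts: gzip FASTQ (pair of files in PE mode), a
fragment manifest, a truth sidecar and a YAML copy of the configuration. All
randomness derives from the config seed through fixed child streams, so a
run is byte-reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .barcodes import (
    BarcodeWhitelist,
    assign_barcodes,
    build_default_whitelist,
)
from .fragments import simulate_fragments, write_fragment_manifest
from .genome import DiploidGenome
from .presets import SimulationConfig
from .reads import (
    FastqWriter,
    QualityModel,
    calibrate_error_scale,
    simulate_pe_reads,
    simulate_se_reads,
)

NULL_TAG = "0_0_0"  # barcode tag of unbarcoded (plain Illumina) libraries


def simulate_library(
    genome: DiploidGenome,
    config: SimulationConfig,
    out_prefix,
    whitelist: Optional[BarcodeWhitelist] = None,
    qmodel: Optional[QualityModel] = None,
    truth_sidecar: bool = True,
) -> dict:
    """Simulate one library and write its artefacts under ``out_prefix``.

    Returns a summary dict with counts and output paths. The default
    whitelist is the fixed 1536-entry list (independent of the run seed, as
    the real barcode list is a platform constant); pass a loaded whitelist to
    use the genuine sequences.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    fragments = simulate_fragments(genome, config.to_fragment_plan())
    if config.barcode_on and fragments:
        if whitelist is None:
            whitelist = build_default_whitelist()
        assign_barcodes(fragments, whitelist, nfl=config.nfl, seed=config.seed)

    params = config.to_read_params()
    if qmodel is None:
        qmodel = QualityModel.default(config.rl)
    scale = calibrate_error_scale(qmodel, config.error_rate)

    n_pairs = 0
    skipped = 0
    serial = 0
    with FastqWriter(out_prefix, config.mode, truth_sidecar, config.bx_tag) as writer:
        for frag in fragments:
            if config.barcode_on and frag.barcode is not None:
                tag = frag.barcode.tag
                bx = frag.barcode.sequence(whitelist) if config.bx_tag else None
            else:
                tag, bx = NULL_TAG, None
            if config.mode == "PE":
                pairs = simulate_pe_reads(
                    frag, genome, params, qmodel, scale,
                    serial_start=serial, barcode_tag=tag, barcode_seq=bx,
                )
                if not pairs:
                    skipped += 1
                    continue
                for pair in pairs:
                    writer.write_pair(pair)
                serial += len(pairs)
                n_pairs += len(pairs)
            else:
                reads = simulate_se_reads(
                    frag, genome, params, qmodel, scale,
                    serial_start=serial, barcode_tag=tag, barcode_seq=bx,
                )
                if not reads:
                    skipped += 1
                    continue
                for read in reads:
                    writer.write_read(read)
                serial += len(reads)
        n_reads = writer.n_reads
        fastq_paths = [str(p) for p in writer.paths]
        truth_path = str(writer.truth_path) if writer.truth_path else None

    manifest_path = Path(f"{out_prefix}.fragments.tsv")
    write_fragment_manifest(fragments, manifest_path)
    config_path = Path(f"{out_prefix}.config.yaml")
    config.to_yaml(config_path)

    return {
        "n_fragments": len(fragments),
        "n_reads": n_reads,
        "n_pairs": n_pairs if config.mode == "PE" else None,
        "skipped_fragments": skipped,
        "fastq": fastq_paths,
        "truth": truth_path,
        "fragment_manifest": str(manifest_path),
        "config": str(config_path),
    }
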