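"""Exception types shared across the package."""


class LinkedSimError(Exception):
    """Base class for all linkedsim errors."""


class FastaFormatError(LinkedSimError, ValueError):
    """Malformed or empty FASTA input, or an illegal sequence character."""


class WhitelistFormatError(LinkedSimError, ValueError):
    """Malformed barcode whitelist file."""


class BarcodeCapacityError(LinkedSimError, ValueError):
    """More partitions requested than the combination space can supply."""


class UnsatisfiablePlanError(LinkedSimError, ValueError):
    """A fragment plan that cannot be fulfilled on the given genome."""


class PlacementError(LinkedSimError, ValueError):
    """Variants could not be placed without overlap."""


class ConsistencyError(LinkedSimError, ValueError):
    """Cross-file inconsistency between manifests, sidecars and FASTQ."""
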