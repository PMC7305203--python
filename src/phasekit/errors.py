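"""Exception hierarchy shared across phasekit modules."""


class PhasekitError(Exception):
    """Base class for all phasekit errors."""


class VcfParseError(PhasekitError):
    """Malformed VCF content; message names the offending line number."""


class VcfFormatError(PhasekitError):
    """Structurally valid VCF that violates the GT-only contract."""


class PedigreeError(PhasekitError):
    """Malformed PED content (duplicate ids, parent cycles, bad columns)."""


class AlignmentError(PhasekitError):
    """Ragged or otherwise invalid multiple alignment."""


class TranscriptError(PhasekitError):
    """Invalid transcript model or coordinate outside the locus slice."""


class UnsupportedVariantError(PhasekitError):
    """Variant class outside the supported set (e.g. indels for
    codon-consequence calling). Raised explicitly, never silently skipped."""


class StatsError(PhasekitError):
    """Undefined statistic for the given table (e.g. zero margin)."""


class SimulationError(PhasekitError):
    """Invalid simulation configuration."""


class StructureParseError(PhasekitError):
    """Unparseable fixed-width structure (PDB) record; names the line."""
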