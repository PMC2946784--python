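"""Exception hierarchy shared across the package."""


class TapHunterError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TapHunterError):
    """Malformed input file (FASTA, labeled CSV, subset list, score table)."""


class ValidationError(TapHunterError):
    """Domain-object invariant violated (bad residue, length, duplicate label...)."""


class ConfigError(TapHunterError):
    """Invalid encoding / model configuration (illegal position, bad kernel...)."""


class EncodingError(TapHunterError):
    """A peptide could not be mapped into feature space."""


class TrainingError(TapHunterError):
    """SVM training impossible (single class, non-finite features)."""
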