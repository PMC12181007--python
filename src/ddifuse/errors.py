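"""Exception hierarchy shared across the package."""


class DDIFuseError(Exception):
    """Base class for all package-specific errors."""


class UnparsableSmiles(DDIFuseError):
    """SMILES string rejected by the chemistry toolkit or the tokenizer."""


class EmptyMolecule(DDIFuseError):
    """SMILES parsed to a molecule with zero heavy atoms."""


class MissingColumn(DDIFuseError):
    """A required column is absent from an input table."""


class DuplicateDrugId(DDIFuseError):
    """The same drug identifier appears twice in a drug table."""


class UnknownDrugReference(DDIFuseError):
    """A pair table references a drug id absent from the drug table."""


class NonBinaryLabel(DDIFuseError):
    """A pair label is not 0 or 1."""


class EmptyCorpus(DDIFuseError):
    """Vocabulary construction was given no SMILES strings."""


class AllPadSequence(DDIFuseError):
    """A token sequence with true_length 0 reached an encoder."""


class DimensionMismatch(DDIFuseError):
    """Tensor shapes incompatible with the requested operation."""


class EmptyBatch(DDIFuseError):
    """A loss or metric was requested on zero samples."""


class DatasetTooSmall(DDIFuseError):
    """Too few pairs to produce non-empty train/valid/test splits."""


class SingleClassTestSet(DDIFuseError):
    """AUROC requested on a test set containing a single class."""


class NaNLoss(DDIFuseError):
    """Training loss became non-finite."""


class GenerationFailure(DDIFuseError):
    """Synthetic molecule generation failed after bounded retries."""


class InsufficientPositives(DDIFuseError):
    """The planted interaction rule yields too few positive pairs."""


class ConfigurationError(DDIFuseError):
    """Invalid model configuration (e.g. no channel enabled)."""
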