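"""Exception hierarchy for phcqual."""


class PhcqualError(Exception):
    """Base class for all phcqual errors."""


class ConfigError(PhcqualError, ValueError):
    """Invalid configuration (bad probability, cluster spec, exclusivity rule...)."""


class SchemaError(PhcqualError, ValueError):
    """Catalogue or table violates the published schema."""


class ShapeError(PhcqualError, ValueError):
    """Dimension mismatch between conformable objects."""


class UnidentifiableModelError(PhcqualError, ValueError):
    """Latent-trait model cannot be identified (e.g. all items zero-variance)."""


class ReliabilityError(PhcqualError, ValueError):
    """Reliability coefficient undefined (<2 items, zero total variance...)."""


class DegenerateClusterError(PhcqualError, ValueError):
    """Cluster-robust quantity undefined (fewer than two clusters)."""


class PipelineError(PhcqualError, RuntimeError):
    """A pipeline stage failed; message names the stage and offending object."""
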