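"""Exception hierarchy shared across the pipeline stages."""


class ImplinetError(Exception):
    """Base class for all implinet-specific failures."""


class DegenerateInput(ImplinetError):
    """Input has no usable variation (e.g. zero-variance expression row)."""


class InsufficientSamples(ImplinetError):
    """Too few samples (or group members) to run the requested statistic."""


class MissingGene(ImplinetError):
    """One or more required gene symbols are absent from the input.

    The missing symbols are stored on ``.genes``.
    """

    def __init__(self, genes):
        self.genes = sorted(genes)
        super().__init__(f"missing genes: {', '.join(self.genes)}")


class DegenerateControls(ImplinetError):
    """Essential and non-essential control medians coincide in a cell line."""


class ModelError(ImplinetError):
    """A model fit failed or did not converge; diagnostics in the message."""


class StratumError(ImplinetError):
    """A survival stratum is empty or has no events."""


class InvalidActivity(ImplinetError):
    """A drug-activity value is non-positive or the dose window is invalid."""


class EmptySignature(ImplinetError):
    """A query signature would be empty (no genes survive the filters)."""


class ConsistencyError(ImplinetError):
    """Up- and down-regulated lists overlap; offenders stored on ``.genes``."""

    def __init__(self, genes):
        self.genes = sorted(genes)
        super().__init__(f"genes in both up and down lists: {', '.join(self.genes)}")
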