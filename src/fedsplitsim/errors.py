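"""Exception types shared across the simulator."""


class FedSplitSimError(Exception):
    """Base class for all simulator errors."""


class ConfigurationError(FedSplitSimError):
    """A config value is out of range or internally inconsistent."""


class ShapeError(FedSplitSimError):
    """Tensor shape incompatible with a layer; message names the layer."""


class DegenerateDataError(FedSplitSimError):
    """Data cannot support the requested statistic (e.g. zero variance)."""


class AggregationError(FedSplitSimError):
    """Parameter sets passed to an aggregator are not shape-compatible."""


class ProtocolStallError(FedSplitSimError):
    """A training round has no eligible clients; the run cannot proceed."""


class UndefinedMetricError(FedSplitSimError):
    """A classification metric's denominator is zero; the value is undefined
    (deliberately distinct from reporting 0.0)."""
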