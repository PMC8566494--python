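"""Exception hierarchy for epilayout."""


class EpilayoutError(Exception):
    """Base class for all package errors."""


class MeasurementError(EpilayoutError):
    """Invalid forearm measurements (non-positive, or inconsistent)."""


class TemplateError(EpilayoutError):
    """Invalid anatomical template or baseline infeasible under it."""


class ConfigError(EpilayoutError):
    """Invalid weights, bounds, modality selection or optimizer settings."""


class DegenerateGeometryError(EpilayoutError):
    """Degenerate geometric input (collinear hull, zero-length segment, ...)."""


class DomainError(EpilayoutError):
    """Argument outside the mathematical domain of a cost curve."""


class RoleError(EpilayoutError):
    """Electrode passed to a cost function with the wrong modality role."""


class InfeasibleRegionError(EpilayoutError):
    """No valid layout could be sampled inside the given region."""


class SelectionError(EpilayoutError):
    """No design in a sweep satisfies the selection rule."""


class DesignFileError(EpilayoutError):
    """Malformed or unsupported design / template file."""
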