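"""Exception hierarchy shared across the package."""


class HelixSynergyError(Exception):
    """Base class for all package errors."""


class InputError(HelixSynergyError, ValueError):
    """Invalid argument values (non-finite coordinates, empty grids, ...)."""


class ConfigError(HelixSynergyError, ValueError):
    """Invalid configuration (out-of-range thresholds, unknown keys, ...)."""


class FormatError(HelixSynergyError, ValueError):
    """Malformed file content (PDB, tables)."""


class SelectionError(HelixSynergyError, KeyError):
    """An atom/chain/residue selection matched nothing."""


class CapacityError(HelixSynergyError, ValueError):
    """A hard size limit was exceeded (state enumeration, chain ids)."""


class NumericalError(HelixSynergyError, ArithmeticError):
    """A numerical procedure failed (degenerate geometry, singular fit)."""
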