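"""Exception hierarchy shared across the package."""


class PyrmatchError(Exception):
    """Base class for all package-specific errors."""


class InvalidSequenceError(PyrmatchError, ValueError):
    """A codon, CDS or protein sequence violates its alphabet/length contract."""


class ScaleError(PyrmatchError, ValueError):
    """A propensity scale is incomplete or a residue is missing from it."""


class ZeroVarianceError(PyrmatchError, ArithmeticError):
    """Pearson correlation requested on a constant profile (undefined)."""


class ConfigError(PyrmatchError, ValueError):
    """A configuration object or file is internally inconsistent."""


class LogicError(PyrmatchError, RuntimeError):
    """An operation was requested on a state where it is undefined
    (e.g. excluding the only reduced class of a residue)."""
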