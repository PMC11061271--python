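"""Exception hierarchy shared across the package."""


class FamsegError(Exception):
    """Base class for all errors raised by famseg."""


class PedigreeError(FamsegError):
    """Structural problem in a pedigree (unresolved parents, loops, probands)."""


class DataFormatError(FamsegError):
    """Malformed or inconsistent input data (files, tables, grids)."""


class ComplexityError(FamsegError):
    """Pedigree too entangled for the exact likelihood engines."""
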