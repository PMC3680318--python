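"""Exception types shared across the package.

The CLI maps these onto exit codes: ParameterError -> 2, FormatError -> 3.
"""


class MiteScoutError(Exception):
    """Base class for all package errors."""


class ParameterError(MiteScoutError, ValueError):
    """A parameter violates its documented domain."""


class FormatError(MiteScoutError, ValueError):
    """An input file is malformed (empty, duplicate ids, bad residues...)."""
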