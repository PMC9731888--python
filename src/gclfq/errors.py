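"""Exception hierarchy shared by all pipeline stages.

``InputError`` covers anything a user can fix (bad residue letters, missing
files, malformed tables) and maps to exit code 1 on the command line;
everything else is an internal error (exit code 2).
"""


class GclfqError(Exception):
    """Base class for all errors raised by this package."""


class InputError(GclfqError):
    """Invalid user input: sequences, tables, configuration or file paths."""


class CapacityUndefinedError(GclfqError):
    """Every peptide of every isoform was filtered out, so the gene has no
    peptide capacity and must be excluded from iBAQ."""


class ConfigError(InputError):
    """Inconsistent pipeline configuration (e.g. quantified gene without a
    capacity entry, missing design file)."""
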