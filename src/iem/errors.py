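"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: input/format problems exit 1,
parameterization problems exit 2, missing external tools exit 3.
"""


class IemError(Exception):
    """Base class for all package errors."""


class InputError(IemError):
    """Unreadable, empty or otherwise unusable input file."""


class EmptyStructureError(InputError):
    """A coordinate file with no ATOM records."""


class FormatError(InputError):
    """A file that exists but violates its declared format."""


class UsageError(IemError):
    """Invalid argument or keyword passed to an operation."""


class ParameterizationError(IemError):
    """Atoms required for an energy calculation lack parameters."""


class MappingError(IemError):
    """A conservation profile cannot be mapped onto a chain sequence."""


class EnvironmentToolError(IemError):
    """An optional external tool or database is not available."""


class DegenerateGeometryError(IemError):
    """Zero interatomic distance or similar geometric degeneracy."""
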