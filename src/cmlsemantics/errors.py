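"""Exception hierarchy for the CML semantic layer."""


class CMLError(Exception):
    """Base class for all package errors."""


class CMLParseError(CMLError):
    """Malformed XML input; carries the 1-based line number when known."""

    def __init__(self, message, line=None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line


class ViewError(CMLError):
    """A typed view was requested for an element of the wrong name."""


class MalformedReferenceError(CMLError):
    """A reference attribute value is not a prefix:local QName."""

    def __init__(self, value):
        super().__init__(f"not a QName (expected exactly one ':' with non-empty "
                         f"NCName parts): {value!r}")
        self.value = value


class UnboundPrefixError(CMLError):
    """A QName prefix has no namespace binding in scope or in the catalog."""

    def __init__(self, prefix, in_scope=()):
        known = ", ".join(sorted(in_scope)) or "none"
        super().__init__(f"prefix {prefix!r} is not bound (in scope: {known})")
        self.prefix = prefix


class UnresolvableURIError(CMLError):
    """A URI does not start with any catalogued namespace."""


class CatalogError(CMLError):
    """A catalog file is malformed or maps a namespace to a missing path."""


class DictionaryLoadError(CMLError):
    """A dictionary failed its own convention validation; .report attached."""

    def __init__(self, message, report):
        super().__init__(message)
        self.report = report


class UnknownDictionaryError(CMLError):
    """No dictionary is registered for the referenced namespace."""


class MissingEntryError(CMLError):
    """The referenced id exists in no dictionary on the lookup chain."""


class UnknownUnitError(CMLError):
    """A unit reference resolves to no registered unit definition."""


class IncompatibleUnitsError(CMLError):
    """Source and target units have unequal dimensions (or annotations)."""


class UnknownPrefixError(CMLError):
    """Not one of the 20 SI multiplier prefixes."""


class AffineUnitError(CMLError):
    """Operation not defined for units with a nonzero offset."""


class InapplicableMutationError(CMLError):
    """A mutation spec cannot be applied to the given base document."""
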