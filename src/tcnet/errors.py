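"""Exception hierarchy for tcnet.

All exceptions derive from :class:`TCNetError` so callers can catch the
library's failures with a single ``except`` clause.  Subclasses also derive
from the closest builtin exception (``ValueError``, ``KeyError``, ...) to
behave well in generic code.
"""


class TCNetError(Exception):
    """Base class of every exception raised by tcnet."""


class ParameterError(TCNetError, ValueError):
    """A scalar parameter (n, k, class name, ...) is out of range."""


class MissingNodeError(TCNetError, KeyError):
    """A NodeRef does not exist in the network."""


class MissingEdgeError(TCNetError, KeyError):
    """An EdgeRef does not exist in the network."""


class MissingTaxonError(TCNetError, KeyError):
    """A taxon label is not present in the network."""


class LabelError(TCNetError, ValueError):
    """A leaf label is duplicated or otherwise unusable."""


class OperationDomainError(TCNetError, ValueError):
    """An operation was applied outside its domain (e.g. on a reticulate edge)."""


class RotationInadmissibleError(OperationDomainError):
    """A child rotation was requested at a parent that is an ancestor of the
    other parent."""


class StructuralError(TCNetError, ValueError):
    """Graph surgery would produce a structurally broken network
    (e.g. parallel edges after smoothing)."""


class ContractError(TCNetError, RuntimeError):
    """An internal post-condition failed; indicates a bug or misuse."""


class UnsupportedClassError(TCNetError, ValueError):
    """The operation is only certified for a restricted network class."""


class FormatError(TCNetError, ValueError):
    """A serialized network could not be parsed.

    Attributes
    ----------
    pos : int or None
        0-based character offset of the problem in the input, when known.
    """

    def __init__(self, message, pos=None):
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)
        self.pos = pos


class ResourceLimitError(TCNetError, RuntimeError):
    """An enumeration exceeded its configured size guard."""


class DuplicateNetworkError(TCNetError, RuntimeError):
    """The uniqueness verification pass found two isomorphic networks."""
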