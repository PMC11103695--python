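"""Exception hierarchy.

Every error raised by the package derives from :class:`DqtError`, so callers
can catch the whole family with one clause while tests pin the precise type.
"""


class DqtError(Exception):
    """Base class for all package errors."""


class FormatError(DqtError):
    """A system bundle is malformed (missing dataset, bad layout)."""


class AnnotationError(DqtError):
    """The atom annotation table is inconsistent with the matrices."""


class ValidationError(DqtError):
    """A matrix violates a structural requirement (e.g. Hermiticity)."""


class ConfigurationError(DqtError):
    """A required piece of configuration (e.g. n_occupied) is missing."""


class ParameterError(DqtError):
    """A model parameter is out of its admissible range."""


class SequenceError(DqtError):
    """A base string contains characters outside {A, C, G, T}."""


class TopologyError(DqtError):
    """An origami topology is invalid (e.g. crossover at a terminal)."""


class SchemeError(DqtError):
    """A contact specification is inconsistent."""


class CatalogError(SchemeError):
    """Terminal annotations are insufficient to enumerate contact schemes."""


class NearSingularOverlapError(DqtError):
    """The overlap matrix is (numerically) singular.

    Attributes
    ----------
    min_eigenvalue : float
        The offending smallest eigenvalue of the overlap matrix.
    """

    def __init__(self, min_eigenvalue: float, tol: float):
        self.min_eigenvalue = float(min_eigenvalue)
        self.tol = float(tol)
        super().__init__(
            f"overlap matrix is near-singular: min eigenvalue "
            f"{min_eigenvalue:.3e} <= tolerance {tol:.1e}"
        )


class NearSingularityError(DqtError):
    """(E + i eta) I - H - Sigma could not be inverted at machine precision."""


class IllConditionedError(DqtError):
    """The Buttiker W matrix is too ill-conditioned to solve reliably.

    Attributes
    ----------
    energy : float
        Energy (eV) at which the condition number blew up.
    cond : float
        Estimated condition number.
    """

    def __init__(self, energy: float, cond: float):
        self.energy = float(energy)
        self.cond = float(cond)
        super().__init__(
            f"W matrix ill-conditioned (cond={cond:.3e}) at E={energy:.6f} eV; "
            "a probe may be fully decoupled from both contacts"
        )


class InterpolationRangeError(DqtError):
    """The requested Fermi energy lies outside the computed energy grid."""


class NotSupportedError(DqtError):
    """Requested a variant outside the implemented model (e.g. non-diagonal broadening)."""
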