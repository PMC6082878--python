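"""Exception hierarchy shared across the package."""


class HybridscanError(Exception):
    """Base class for all package-specific errors."""


class AlignmentShapeError(HybridscanError):
    """Sequences in one locus alignment differ in length."""


class DuplicateTaxonError(HybridscanError):
    """A taxon label occurs more than once in an alignment."""


class TooFewTaxaError(HybridscanError):
    """An operation needs more leaves than the tree provides."""


class BipartitionDomainError(HybridscanError):
    """Bipartitions live on unrelated (disjoint) taxon sets."""


class ModelValidationError(HybridscanError):
    """A simulation model or introgression event is inconsistent."""


class NoInformativeSitesError(HybridscanError):
    """A D test found zero ABBA or BABA signal."""

    def __init__(self, message: str, n_sites_used: int = 0):
        super().__init__(message)
        self.n_sites_used = n_sites_used


class DegenerateBootstrapWarning(UserWarning):
    """Bootstrap SD collapsed to zero; Z reported as signed infinity."""


class ConfigurationError(HybridscanError):
    """Invalid user-supplied analysis configuration."""


class SaturatedDistanceError(HybridscanError):
    """A pairwise p-distance is beyond the Jukes-Cantor ceiling (>= 0.75)."""

    def __init__(self, message: str, pair: tuple[str, str]):
        super().__init__(message)
        self.pair = pair


class DegenerateTraitError(HybridscanError):
    """A discrete trait is monomorphic; the Mk rate is unidentifiable."""
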