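"""Exception hierarchy shared across the package."""


class GwasVizError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GwasVizError):
    """Input data violates a contract (missing columns, bad values, ...)."""


class MissingColumnError(ValidationError):
    """One or more mandatory column roles could not be resolved."""

    def __init__(self, roles):
        self.roles = sorted(roles)
        super().__init__(
            "could not resolve mandatory column role(s): " + ", ".join(self.roles)
        )


class AmbiguousColumnError(ValidationError):
    """Two or more header columns resolve to the same column role."""

    def __init__(self, role, columns):
        self.role = role
        self.columns = list(columns)
        super().__init__(
            f"columns {self.columns} all resolve to the {role!r} role; rename or drop one"
        )


class RegionParseError(GwasVizError):
    """A region string could not be parsed as 'chrom:start-end'."""


class GeneNotFoundError(GwasVizError):
    """A gene symbol is absent from the gene track."""

    def __init__(self, gene, suggestions=()):
        self.gene = gene
        self.suggestions = list(suggestions)
        msg = f"gene {gene!r} not found in the gene track"
        if self.suggestions:
            msg += "; did you mean: " + ", ".join(self.suggestions) + "?"
        super().__init__(msg)


class VariantNotFoundError(GwasVizError):
    """A variant identifier is absent from the dataset."""
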