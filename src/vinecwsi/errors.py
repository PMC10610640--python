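"""Exception hierarchy shared across the pipeline."""


class ContractError(ValueError):
    """An input violates a documented precondition."""


class MissingMetadataError(ContractError):
    """A file lacks required metadata (georeferencing, CRS, declared columns)."""


class CrsMismatchError(ContractError):
    """Two spatial inputs carry different CRS labels."""


class DegenerateGeometryError(ContractError):
    """Geometry too degenerate for the requested operation (collinear, coplanar, n too small)."""

    def __init__(self, message: str, n_points: int | None = None):
        super().__init__(message)
        self.n_points = n_points
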