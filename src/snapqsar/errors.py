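"""Exception types shared across the pipeline."""


class SnapQsarError(Exception):
    """Base class for all package errors."""


class LibraryFormatError(SnapQsarError):
    """The molecule library file is malformed (missing column, bad row)."""


class EmbeddingError(SnapQsarError):
    """3D embedding / force-field minimisation failed for one molecule."""

    def __init__(self, mol_id: str, message: str):
        self.mol_id = mol_id
        super().__init__(f"{mol_id}: {message}")


class SDFParseError(SnapQsarError):
    """A molecule block in an SDF file could not be parsed."""


class DegenerateLabelsError(SnapQsarError):
    """An operation requiring both classes saw only one."""


class DegenerateControlError(SnapQsarError):
    """Positive-control and DMSO well values coincide; % activity undefined."""


class FixtureGenerationError(SnapQsarError):
    """A synthetic fixture failed its built-in sanity check."""
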