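"""Exception hierarchy shared across the package."""


class TaxonPagesError(Exception):
    """Base class for all package errors."""


class ArticleParseError(TaxonPagesError):
    """Malformed article XML; message carries line/column when known."""


class DumpParseError(TaxonPagesError):
    """Malformed MediaWiki export dump."""


class ValidationError(TaxonPagesError):
    """A domain invariant was violated by otherwise well-formed input."""


class RevisionLookupError(TaxonPagesError, LookupError):
    """A revision id is absent from the page history being queried."""


class TitleCollisionError(ValidationError):
    """Two treatments in one article map to the same wiki page title."""
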