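"""Emit MediaWiki pages from taxon treatments.

Each treatment becomes one page: the citation template first, then the
taxonomic-classification template, the treatment sections as level-2
headings in source order, identification keys, figures, the reference list,
and the external-resource link hub.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass

from taxonpages.citation import (
    PLACEHOLDER_CONTRIBUTORS,
    PLACEHOLDER_DATE,
    PLACEHOLDER_REVISION,
    TemplateCall,
)
from taxonpages.config import SiteConfig
from taxonpages.errors import TitleCollisionError, ValidationError
from taxonpages.revision_history import generic_url
from taxonpages.taxpub_reader import (
    ArticleMeta,
    Block,
    BlockKind,
    IdentificationKey,
    TaxonName,
    TaxPubArticle,
    Treatment,
)
from taxonpages.wikitext import check_balanced, escape

logger = logging.getLogger(__name__)

__all__ = [
    "WikiPage",
    "TemplateCall",
    "ResourceRegistry",
    "page_title",
    "emit_page",
    "emit_key",
    "external_links",
    "emit_article",
]


@dataclass(frozen=True)
class ResourceRegistry:
    """Ordered registry of external biodiversity resources.

    Each entry is ``(resource name, URL template)`` where the template
    contains exactly one ``{name}`` placeholder.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        for name, template in self.entries:
            if template.count("{name}") != 1:
                raise ValidationError(
                    f"registry entry {name!r} must contain exactly one {{name}} placeholder"
                )

    @classmethod
    def from_config(cls, config: SiteConfig) -> "ResourceRegistry":
        return cls(entries=tuple(config.resources))


@dataclass(frozen=True)
class WikiPage:
    """A page title plus its MediaWiki markup and image transfer list."""

    title: str
    markup: str
    #: (source filename from the article, target wiki file name) pairs.
    images: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if " " in self.title:
            raise ValidationError(f"page title must use underscores, not spaces: {self.title!r}")
        problems = check_balanced(self.markup)
        if problems:
            raise ValidationError(f"page {self.title!r} markup unbalanced: {'; '.join(problems)}")


def page_title(taxon: TaxonName) -> str:
    """Wiki page title for a taxon: name parts joined by underscores.

    ``Sinocallipus catba`` -> ``Sinocallipus_catba``.
    """
    if not taxon.genus:
        raise ValidationError("cannot build a page title without a genus")
    parts = [taxon.genus[0].upper() + taxon.genus[1:]]
    if taxon.species_epithet:
        parts.append(taxon.species_epithet.lower())
        if taxon.infraspecific_epithet:
            parts.append(taxon.infraspecific_epithet.lower())
    return "_".join(parts)


def external_links(taxon: TaxonName, registry: ResourceRegistry) -> list[tuple[str, str]]:
    """One (resource, URL) per registry entry, in registry order.

    The ``{name}`` placeholder receives the percent-encoded space-separated
    name ("Genus species").
    """
    encoded = urllib.parse.quote(taxon.binomial, safe="")
    return [(name, template.format(name=encoded)) for name, template in registry.entries]


def emit_key(key: IdentificationKey) -> str:
    """Render a dichotomous key as a wiki table, one row per lead.

    Taxon outcomes become internal links; next-couplet outcomes become
    anchor links to the target couplet's first row.
    """
    key.validate()
    lines = ['{| class="wikitable"', "! # !! Lead !! Outcome"]
    for couplet in key.couplets:
        for i, lead in enumerate(couplet.leads):
            anchor = f' id="couplet-{couplet.number}"' if i == 0 else ""
            if lead.taxon:
                genus, _, rest = lead.taxon.partition(" ")
                target = "_".join([genus] + rest.split()) if rest else genus
                outcome = f"[[{target}|{escape(lead.taxon)}]]"
            else:
                outcome = f"[[#couplet-{lead.next_couplet}|{lead.next_couplet}]]"
            lines.append(f"|-{anchor}")
            lines.append(f"| {couplet.number} || {escape(lead.text)} || {outcome}")
    lines.append("|}")
    return "\n".join(lines)


def _render_block(block: Block) -> str:
    if block.kind is BlockKind.PARAGRAPH:
        return escape(block.text)
    if block.kind is BlockKind.FIGURE_REF:
        label = escape(block.text) if block.text else f"Figure {block.ref}"
        return f"([[#fig-{block.ref}|{label}]])"
    if block.kind in (BlockKind.COORDINATE, BlockKind.EXTERNAL_ID):
        if block.url:
            return f"[{block.url} {escape(block.text)}]"
        return escape(block.text)
    raise ValueError(f"unhandled block kind {block.kind}")  # pragma: no cover


def _image_name(title: str, index: int, source_filename: str) -> str:
    ext = source_filename.rsplit(".", 1)[-1].lower() if "." in source_filename else "jpg"
    return f"{title}_fig{index}.{ext}"


def _classification_call(treatment: Treatment, config: SiteConfig) -> TemplateCall:
    # Higher ranks come from the XML when tagged; otherwise the template
    # fields stay blank for wiki-side completion.
    ranks = dict(treatment.classification)
    taxon = treatment.taxon
    params = [
        ("regnum", ranks.get("regnum", "")),
        ("ordo", ranks.get("ordo", "")),
        ("familia", ranks.get("familia", "")),
        ("genus", taxon.genus),
        ("species", taxon.species_epithet),
        ("authorship", taxon.authorship),
    ]
    return TemplateCall(name=config.template("classification"), params=tuple(params))


def _citation_call(meta: ArticleMeta, config: SiteConfig) -> TemplateCall:
    # Journal half from article metadata; wiki-side fields are live template
    # parameters (magic words) so the on-page citation self-updates.
    params = (
        ("authors", ", ".join(meta.authors)),
        ("year", str(meta.year)),
        ("title", meta.title),
        ("journal", meta.journal),
        ("issue", meta.issue_no),
        ("pages", meta.pages),
        ("doi", meta.doi or ""),
        ("date", PLACEHOLDER_DATE),
        ("revision", PLACEHOLDER_REVISION),
        ("contributors", PLACEHOLDER_CONTRIBUTORS),
    )
    return TemplateCall(name=config.template("citation"), params=params)


def emit_page(
    treatment: Treatment,
    meta: ArticleMeta,
    registry: ResourceRegistry | None = None,
    site_config: SiteConfig | None = None,
    title: str | None = None,
) -> WikiPage:
    """Convert one treatment into a :class:`WikiPage`."""
    config = site_config or SiteConfig()
    registry = registry if registry is not None else ResourceRegistry.from_config(config)
    title = title or page_title(treatment.taxon)

    chunks: list[str] = [
        _citation_call(meta, config).to_wikitext(),
        _classification_call(treatment, config).to_wikitext(),
    ]

    if treatment.zoobank_lsid:
        lsid = treatment.zoobank_lsid
        chunks.append(f"ZooBank LSID: [http://zoobank.org/{lsid} {escape(lsid)}]")

    for section in treatment.sections:
        body = "\n\n".join(_render_block(b) for b in section.blocks)
        chunks.append(f"== {escape(section.label)} ==" + (f"\n{body}" if body else ""))

    for key in treatment.keys:
        chunks.append("== Identification key ==\n" + emit_key(key))

    images: list[tuple[str, str]] = []
    if treatment.figures:
        fig_lines = ["== Figures =="]
        for i, figure in enumerate(treatment.figures, start=1):
            wiki_name = _image_name(title, i, figure.filename)
            images.append((figure.filename, wiki_name))
            anchor = f'<span id="fig-{figure.id}"></span>' if figure.id else ""
            fig_lines.append(f"{anchor}[[File:{wiki_name}|thumb|{escape(figure.caption)}]]")
        chunks.append("\n".join(fig_lines))

    if treatment.references:
        ref_lines = ["== References =="] + [f"* {escape(r)}" for r in treatment.references]
        chunks.append("\n".join(ref_lines))

    links = external_links(treatment.taxon, registry)
    chunks.append(
        TemplateCall(name=config.template("external_links"), params=tuple(links)).to_wikitext()
    )

    return WikiPage(title=title, markup="\n\n".join(chunks) + "\n", images=tuple(images))


def emit_article(
    article: TaxPubArticle,
    registry: ResourceRegistry | None = None,
    site_config: SiteConfig | None = None,
) -> list[WikiPage]:
    """Emit one page per treatment, in document order.

    Title collisions raise :class:`TitleCollisionError` unless the config
    enables the "_(Author_Year)" disambiguation suffix.
    """
    config = site_config or SiteConfig()
    titles: dict[str, int] = {}
    resolved: list[str] = []
    for index, treatment in enumerate(article.treatments):
        title = page_title(treatment.taxon)
        if title in titles:
            if not config.disambiguate_titles:
                raise TitleCollisionError(
                    f"treatments {titles[title]} and {index} both map to page {title!r}"
                )
            suffix = treatment.taxon.authorship.replace(" & ", "_").replace(", ", "_").replace(" ", "_")
            title = f"{title}_({suffix})" if suffix else f"{title}_({index})"
            logger.warning("title collision resolved with suffix: %s", title)
        titles[title] = index
        resolved.append(title)
    return [
        emit_page(t, article.meta, registry, config, title=resolved[i])
        for i, t in enumerate(article.treatments)
    ]


def backlink_urls(article: TaxPubArticle, site_config: SiteConfig | None = None) -> list[tuple[str, str]]:
    """(taxon name, generic wiki URL) per treatment, for the journal source."""
    config = site_config or SiteConfig()
    return [
        (t.taxon.binomial, generic_url(config, page_title(t.taxon)))
        for t in article.treatments
    ]
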