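"""Parse TaxPub-style NLM XML articles into the domain model.

Supported element subset (normative grammar in ``schemas/taxpub_subset.rnc``)::

    <article>
      <article-meta>
        <title/> <journal/> <issue/> <pages/> <doi/>?
        <year/> <pub-date/>            <!-- pub-date: YYYY-MM-DD -->
        <authors> <author/>+ </authors>
      </article-meta>
      <treatment>*
        <taxon rank="genus|species|subspecies">
          <genus/> <species-epithet/>? <infraspecific-epithet/>?
          <authorship/>? <classification> <rank name="..."/>* </classification>?
        </taxon>
        <zoobank-lsid/>?
        <section label="...">*
          <p/> | <fig-ref rid="..."/> | <coordinate lat= lon= url=/> |
          <ext-id type= url=/>
        </section>
        <key>* <couplet number="N"> <lead to-couplet="M"|taxon="G s"/>+ </couplet>+ </key>
        <figure id="..." filename="...">* <caption/> </figure>
        <references>? <ref/>* </references>
      </treatment>
    </article>

Documents must be UTF-8; all text is normalized to Unicode NFC.  Unknown
elements are flattened to opaque paragraph text and logged, never silently
dropped.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
import unicodedata
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from taxonpages.errors import ArticleParseError, ValidationError

logger = logging.getLogger(__name__)

_MANDATORY_META = ("authors", "year", "title", "journal")


def _nfc(text: str | None) -> str:
    return unicodedata.normalize("NFC", text or "").strip()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArticleMeta:
    """Bibliographic metadata of the source journal article."""

    authors: tuple[str, ...]
    year: int
    title: str
    journal: str
    issue_no: str = ""
    pages: str = ""
    doi: str | None = None
    publication_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.authors:
            raise ValidationError("article must have at least one author")
        current = _dt.date.today().year
        if not 1750 <= self.year <= current:
            raise ValidationError(f"year {self.year} outside [1750, {current}]")
        if self.doi is not None and not self.doi.startswith("10."):
            raise ValidationError(f"DOI must begin with '10.': {self.doi!r}")


class Rank(str, Enum):
    GENUS = "genus"
    SPECIES = "species"
    SUBSPECIES = "subspecies"


@dataclass(frozen=True)
class TaxonName:
    """A genus-group or species-group scientific name."""

    genus: str
    species_epithet: str = ""
    infraspecific_epithet: str = ""
    authorship: str = ""
    rank: Rank = Rank.SPECIES

    def __post_init__(self) -> None:
        object.__setattr__(self, "rank", Rank(self.rank))
        if not self.genus:
            raise ValidationError("genus must be non-empty")
        if not self.genus[0].isupper():
            raise ValidationError(f"genus must be capitalized: {self.genus!r}")
        for epithet in (self.species_epithet, self.infraspecific_epithet):
            if epithet and epithet != epithet.lower():
                raise ValidationError(f"epithets must be lowercase: {epithet!r}")
        expected = Rank.GENUS
        if self.species_epithet:
            expected = Rank.SUBSPECIES if self.infraspecific_epithet else Rank.SPECIES
        elif self.infraspecific_epithet:
            raise ValidationError("infraspecific epithet without species epithet")
        if self.rank is not expected:
            raise ValidationError(
                f"rank {self.rank.value!r} inconsistent with epithets present "
                f"(expected {expected.value!r})"
            )

    @property
    def binomial(self) -> str:
        """Space-separated name parts, e.g. ``Sinocallipus catba``."""
        parts = [self.genus, self.species_epithet, self.infraspecific_epithet]
        return " ".join(p for p in parts if p)


class BlockKind(str, Enum):
    PARAGRAPH = "paragraph"
    FIGURE_REF = "figure-reference"
    COORDINATE = "coordinate"
    EXTERNAL_ID = "external-identifier"


@dataclass(frozen=True)
class Block:
    """One content block inside a treatment section."""

    kind: BlockKind
    text: str = ""
    url: str = ""
    ref: str = ""  # figure id for figure references; type label for ext-ids


@dataclass(frozen=True)
class TreatmentSection:
    label: str
    blocks: tuple[Block, ...] = ()

    def __post_init__(self) -> None:
        if not self.label:
            raise ValidationError("section label must be non-empty")


@dataclass(frozen=True)
class KeyLead:
    text: str
    #: Either the number of the next couplet...
    next_couplet: int | None = None
    #: ...or a terminal taxon name (space-separated binomial).
    taxon: str = ""

    def __post_init__(self) -> None:
        if (self.next_couplet is None) == (not self.taxon):
            raise ValidationError("lead must have exactly one outcome (couplet or taxon)")


@dataclass(frozen=True)
class KeyCouplet:
    number: int
    leads: tuple[KeyLead, ...]

    def __post_init__(self) -> None:
        if not self.leads:
            raise ValidationError(f"couplet {self.number} has no leads")


@dataclass(frozen=True)
class IdentificationKey:
    couplets: tuple[KeyCouplet, ...]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        numbers = [c.number for c in self.couplets]
        if len(numbers) != len(set(numbers)):
            raise ValidationError("couplet numbers must be unique")
        known = set(numbers)
        for couplet in self.couplets:
            for lead in couplet.leads:
                if lead.next_couplet is not None and lead.next_couplet not in known:
                    raise ValidationError(
                        f"couplet {couplet.number} points to missing couplet "
                        f"{lead.next_couplet}"
                    )
        if not any(lead.taxon for c in self.couplets for lead in c.leads):
            raise ValidationError("key must resolve to at least one taxon")


@dataclass(frozen=True)
class Figure:
    id: str
    caption: str
    filename: str


@dataclass(frozen=True)
class Treatment:
    """One taxon treatment: name, identifiers, sections, keys, figures, refs."""

    taxon: TaxonName
    zoobank_lsid: str = ""
    sections: tuple[TreatmentSection, ...] = ()
    references: tuple[str, ...] = ()
    figures: tuple[Figure, ...] = ()
    keys: tuple[IdentificationKey, ...] = ()
    #: Higher-rank classification taken verbatim from the XML when present,
    #: as ordered (rank name, value) pairs; empty otherwise.
    classification: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class TaxPubArticle:
    meta: ArticleMeta
    treatments: tuple[Treatment, ...] = ()


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------


def _load_root(xml_document: str | bytes | os.PathLike) -> ET.Element:
    if isinstance(xml_document, (os.PathLike,)) or (
        isinstance(xml_document, str) and not xml_document.lstrip().startswith("<")
    ):
        data = Path(xml_document).read_bytes()
    elif isinstance(xml_document, bytes):
        data = xml_document
    else:
        data = xml_document.encode("utf-8")
    try:
        return ET.fromstring(data)
    except ET.ParseError as exc:
        line, col = exc.position
        raise ArticleParseError(f"malformed XML at line {line}, column {col}: {exc.msg}") from exc


def _parse_meta(root: ET.Element) -> ArticleMeta:
    meta_el = root.find("article-meta")
    missing = []
    if meta_el is None:
        raise ValidationError(f"missing mandatory fields: {', '.join(_MANDATORY_META)}")

    authors = tuple(
        _nfc(a.text) for a in meta_el.findall("authors/author") if _nfc(a.text)
    )
    title = _nfc(meta_el.findtext("title"))
    journal = _nfc(meta_el.findtext("journal"))
    year_text = _nfc(meta_el.findtext("year"))
    pub_date_text = _nfc(meta_el.findtext("pub-date"))

    pub_date = None
    if pub_date_text:
        try:
            pub_date = _dt.date.fromisoformat(pub_date_text)
        except ValueError as exc:
            raise ValidationError(f"bad pub-date {pub_date_text!r}: {exc}") from exc
    if not year_text and pub_date is not None:
        year_text = str(pub_date.year)

    if not authors:
        missing.append("authors")
    if not year_text:
        missing.append("year")
    if not title:
        missing.append("title")
    if not journal:
        missing.append("journal")
    if missing:
        raise ValidationError(f"missing mandatory fields: {', '.join(missing)}")

    doi = _nfc(meta_el.findtext("doi")) or None
    return ArticleMeta(
        authors=authors,
        year=int(year_text),
        title=title,
        journal=journal,
        issue_no=_nfc(meta_el.findtext("issue")),
        pages=_nfc(meta_el.findtext("pages")),
        doi=doi,
        publication_date=pub_date,
    )


def _parse_taxon(el: ET.Element) -> TaxonName:
    genus = _nfc(el.findtext("genus"))
    species = _nfc(el.findtext("species-epithet"))
    infra = _nfc(el.findtext("infraspecific-epithet"))
    rank_attr = el.get("rank")
    if rank_attr:
        rank = Rank(rank_attr)
    elif infra:
        rank = Rank.SUBSPECIES
    elif species:
        rank = Rank.SPECIES
    else:
        rank = Rank.GENUS
    return TaxonName(
        genus=genus,
        species_epithet=species,
        infraspecific_epithet=infra,
        authorship=_nfc(el.findtext("authorship")),
        rank=rank,
    )


def _flatten(el: ET.Element) -> str:
    return _nfc(" ".join(t.strip() for t in el.itertext() if t.strip()))


def _parse_section(el: ET.Element) -> TreatmentSection:
    blocks: list[Block] = []
    for child in el:
        if child.tag == "p":
            blocks.append(Block(BlockKind.PARAGRAPH, text=_flatten(child)))
        elif child.tag == "fig-ref":
            blocks.append(Block(BlockKind.FIGURE_REF, text=_flatten(child), ref=child.get("rid", "")))
        elif child.tag == "coordinate":
            lat, lon = child.get("lat", ""), child.get("lon", "")
            url = child.get("url", "")
            text = _flatten(child) or (f"{lat}, {lon}" if lat and lon else "")
            blocks.append(Block(BlockKind.COORDINATE, text=text, url=url))
        elif child.tag == "ext-id":
            blocks.append(
                Block(
                    BlockKind.EXTERNAL_ID,
                    text=_flatten(child),
                    url=child.get("url", ""),
                    ref=child.get("type", ""),
                )
            )
        else:
            logger.warning("unknown element <%s> in section %r flattened to text", child.tag, el.get("label"))
            blocks.append(Block(BlockKind.PARAGRAPH, text=_flatten(child)))
    return TreatmentSection(label=_nfc(el.get("label")), blocks=tuple(blocks))


def _parse_key(el: ET.Element) -> IdentificationKey:
    couplets = []
    for c_el in el.findall("couplet"):
        try:
            number = int(c_el.get("number", ""))
        except ValueError as exc:
            raise ValidationError(f"couplet number must be an integer: {c_el.get('number')!r}") from exc
        leads = []
        for l_el in c_el.findall("lead"):
            to = l_el.get("to-couplet")
            leads.append(
                KeyLead(
                    text=_flatten(l_el),
                    next_couplet=int(to) if to is not None else None,
                    taxon=_nfc(l_el.get("taxon")),
                )
            )
        couplets.append(KeyCouplet(number=number, leads=tuple(leads)))
    return IdentificationKey(couplets=tuple(couplets))


def _parse_treatment(el: ET.Element) -> Treatment:
    taxon_el = el.find("taxon")
    if taxon_el is None:
        raise ValidationError("treatment without <taxon> element")
    taxon = _parse_taxon(taxon_el)

    classification = tuple(
        (_nfc(r.get("name")), _flatten(r))
        for r in taxon_el.findall("classification/rank")
    )

    sections: list[TreatmentSection] = []
    figures: list[Figure] = []
    keys: list[IdentificationKey] = []
    references: list[str] = []

    for child in el:
        if child.tag in ("taxon", "zoobank-lsid"):
            continue
        if child.tag == "section":
            sections.append(_parse_section(child))
        elif child.tag == "key":
            keys.append(_parse_key(child))
        elif child.tag == "figure":
            figures.append(
                Figure(
                    id=_nfc(child.get("id")),
                    caption=_nfc(child.findtext("caption")),
                    filename=_nfc(child.get("filename")),
                )
            )
        elif child.tag == "references":
            references.extend(_flatten(r) for r in child.findall("ref"))
        else:
            logger.warning(
                "unknown element <%s> in treatment of %s flattened to a section",
                child.tag,
                taxon.binomial,
            )
            sections.append(
                TreatmentSection(label=child.tag, blocks=(Block(BlockKind.PARAGRAPH, text=_flatten(child)),))
            )

    return Treatment(
        taxon=taxon,
        zoobank_lsid=_nfc(el.findtext("zoobank-lsid")),
        sections=tuple(sections),
        references=tuple(references),
        figures=tuple(figures),
        keys=tuple(keys),
        classification=classification,
    )


def parse_article(xml_document: str | bytes | os.PathLike) -> TaxPubArticle:
    """Parse an article document into a :class:`TaxPubArticle`.

    Parameters
    ----------
    xml_document
        XML text (str or bytes) or a path to a UTF-8 XML file.  A string is
        treated as document content when it starts with ``<``, as a path
        otherwise.

    Raises
    ------
    ArticleParseError
        On malformed XML (message names line and column).
    ValidationError
        When mandatory bibliographic fields are missing (all missing fields
        are listed) or a domain invariant is violated.
    """
    root = _load_root(xml_document)
    if root.tag != "article":
        raise ValidationError(f"root element must be <article>, got <{root.tag}>")
    meta = _parse_meta(root)
    treatments = []
    for child in root:
        if child.tag == "article-meta":
            continue
        if child.tag == "treatment":
            treatments.append(_parse_treatment(child))
        else:
            logger.warning("unknown article-level element <%s> ignored (flattened text: %r)",
                           child.tag, _flatten(child)[:80])
    return TaxPubArticle(meta=meta, treatments=tuple(treatments))


def extract_treatment_names(article: TaxPubArticle) -> list[TaxonName]:
    """Return one :class:`TaxonName` per treatment, in document order."""
    return [t.taxon for t in article.treatments]
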