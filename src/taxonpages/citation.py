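"""Joint journal + versioned-wiki citations and their renderings.

A joint citation is one bibliographic reference with two halves: the static
journal publication and one numbered, time-stamped wiki revision derived from
it, with the wiki contributors credited alongside the journal authors.

Renderings: plain text (the canonical scheme), BibTeX, RIS and a wikitext
cite-template call.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass

from taxonpages.config import SiteConfig
from taxonpages.errors import ValidationError
from taxonpages.revision_history import PageHistory, contributors_at, permanent_url
from taxonpages.taxpub_reader import ArticleMeta
from taxonpages.wikitext import serialize_template

#: Magic-word placeholders used when a template call must self-update on a
#: live wiki instead of pinning one revision.
PLACEHOLDER_REVISION = "{{REVISIONID}}"
PLACEHOLDER_DATE = "{{REVISIONYEAR}}-{{REVISIONMONTH}}-{{REVISIONDAY2}}"
PLACEHOLDER_CONTRIBUTORS = "{{CONTRIBUTORS}}"

FORMATS = ("text", "bibtex", "ris", "wikitext")


@dataclass(frozen=True)
class WikiVersionRef:
    """The wiki half of a joint citation: one pinned page revision."""

    date: _dt.date
    rev_id: int
    permanent_url: str
    contributors: tuple[str, ...]

    def __post_init__(self) -> None:
        if f"oldid={self.rev_id}" not in self.permanent_url:
            raise ValidationError(
                f"permanent_url must contain 'oldid={self.rev_id}': {self.permanent_url!r}"
            )


@dataclass(frozen=True)
class JointCitation:
    """Journal article + versioned wiki page as a single reference."""

    source: ArticleMeta
    wiki: WikiVersionRef


@dataclass(frozen=True)
class TemplateCall:
    """A wiki template invocation with ordered, unique parameter keys."""

    name: str
    params: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        keys = [k for k, _ in self.params]
        if len(keys) != len(set(keys)):
            raise ValidationError(f"duplicate template parameter keys in {{{{{self.name}}}}}")

    def to_wikitext(self) -> str:
        return serialize_template(self.name, list(self.params))


def build_joint_citation(
    meta: ArticleMeta,
    history: PageHistory,
    rev_id: int,
    site_config: SiteConfig,
) -> JointCitation:
    """Assemble the joint citation for one revision of one page.

    The citation is derived entirely from export artifacts: article metadata
    plus the page history.  The date is the UTC date of the cited revision's
    timestamp; contributors are attributed by revision participation up to
    and including ``rev_id``, alphabetically, excluding bots when the config
    says so.
    """
    revision = history.revision(rev_id)  # raises RevisionLookupError if absent
    contributors = contributors_at(history, rev_id, exclude_bots=site_config.exclude_bots)
    return JointCitation(
        source=meta,
        wiki=WikiVersionRef(
            date=revision.timestamp.astimezone(_dt.timezone.utc).date(),
            rev_id=rev_id,
            permanent_url=permanent_url(site_config, history.title, rev_id),
            contributors=tuple(contributors),
        ),
    )


def _authors_text(meta: ArticleMeta) -> str:
    return ", ".join(meta.authors)


def _contributors_text(citation: JointCitation, empty_token: str) -> str:
    return ", ".join(citation.wiki.contributors) or empty_token


def render_text(citation: JointCitation, empty_token: str = "none") -> str:
    """Canonical single-reference text form.

    Grammar: ``<authors> (<year>) <title> <journal> <issue> <pages> <doi>.
    Versioned wiki page: <YYYY-MM-DD>, version <rev>, <permanent url>,
    contributors (alphabetical order): <names>.``  Absent fields (DOI, issue,
    pages) are omitted with single spaces preserved.
    """
    meta = citation.source
    head_parts = [
        _authors_text(meta),
        f"({meta.year})",
        meta.title,
        meta.journal,
        meta.issue_no,
        meta.pages,
        meta.doi or "",
    ]
    head = " ".join(p for p in head_parts if p)
    wiki = citation.wiki
    return (
        f"{head}. Versioned wiki page: {wiki.date.isoformat()}, "
        f"version {wiki.rev_id}, {wiki.permanent_url}, "
        f"contributors (alphabetical order): {_contributors_text(citation, empty_token)}."
    )


_KEY_SANITIZE = re.compile(r"[^A-Za-z0-9]+")


def _bibtex_key(meta: ArticleMeta) -> str:
    surname = meta.authors[0].split()[0]
    return f"{_KEY_SANITIZE.sub('', surname)}{meta.year}"


def _bibtex_escape(value: str) -> str:
    # Our values never legitimately contain braces; strip rather than risk
    # an unbalanced entry.
    return value.replace("{", "(").replace("}", ")")


def render_bibtex(citation: JointCitation, empty_token: str = "none") -> str:
    meta = citation.source
    wiki = citation.wiki
    fields: list[tuple[str, str]] = [
        ("author", " and ".join(meta.authors)),
        ("year", str(meta.year)),
        ("title", meta.title),
        ("journal", meta.journal),
    ]
    if meta.issue_no:
        fields.append(("number", meta.issue_no))
    if meta.pages:
        fields.append(("pages", meta.pages))
    if meta.doi:
        fields.append(("doi", meta.doi))
    fields += [
        ("url", wiki.permanent_url),
        (
            "note",
            f"Versioned wiki page: {wiki.date.isoformat()}, version {wiki.rev_id}, "
            f"contributors (alphabetical order): {_contributors_text(citation, empty_token)}",
        ),
    ]
    body = ",\n".join(f"  {k} = {{{_bibtex_escape(v)}}}" for k, v in fields)
    return f"@misc{{{_bibtex_key(meta)},\n{body}\n}}\n"


def render_ris(citation: JointCitation, empty_token: str = "none") -> str:
    meta = citation.source
    wiki = citation.wiki
    lines = ["TY  - JOUR"]
    lines += [f"AU  - {a}" for a in meta.authors]
    lines.append(f"PY  - {meta.year}")
    lines.append(f"TI  - {meta.title}")
    lines.append(f"JO  - {meta.journal}")
    if meta.issue_no:
        lines.append(f"IS  - {meta.issue_no}")
    if meta.pages:
        lines.append(f"SP  - {meta.pages}")
    if meta.doi:
        lines.append(f"DO  - {meta.doi}")
    lines.append(f"UR  - {wiki.permanent_url}")
    lines.append(
        f"N1  - Versioned wiki page: {wiki.date.isoformat()}, version {wiki.rev_id}, "
        f"contributors (alphabetical order): {_contributors_text(citation, empty_token)}"
    )
    lines.append("ER  - ")
    return "\n".join(lines) + "\n"


def citation_template_call(
    citation: JointCitation,
    site_config: SiteConfig | None = None,
    placeholder_mode: bool = False,
) -> TemplateCall:
    """Template call carrying one parameter per citation scheme field.

    With ``placeholder_mode`` the wiki-side fields (date, revision,
    contributors) carry magic-word placeholders so the template self-updates
    on every page view instead of pinning one revision.
    """
    cfg = site_config or SiteConfig()
    meta = citation.source
    wiki = citation.wiki
    if placeholder_mode:
        date, revision, contributors = (
            PLACEHOLDER_DATE,
            PLACEHOLDER_REVISION,
            PLACEHOLDER_CONTRIBUTORS,
        )
    else:
        date = wiki.date.isoformat()
        revision = str(wiki.rev_id)
        contributors = _contributors_text(citation, cfg.empty_contributors_token)
    params: tuple[tuple[str, str], ...] = (
        ("authors", _authors_text(meta)),
        ("year", str(meta.year)),
        ("title", meta.title),
        ("journal", meta.journal),
        ("issue", meta.issue_no),
        ("pages", meta.pages),
        ("doi", meta.doi or ""),
        ("url", wiki.permanent_url),
        ("date", date),
        ("revision", revision),
        ("contributors", contributors),
    )
    return TemplateCall(name=cfg.template("citation"), params=params)


def render_wikitext(citation: JointCitation, site_config: SiteConfig | None = None) -> str:
    """A ready-to-copy cite-template call for use on another wiki."""
    cfg = site_config or SiteConfig()
    call = citation_template_call(citation, cfg)
    return TemplateCall(name=cfg.template("cite_wiki"), params=call.params).to_wikitext() + "\n"


def render(citation: JointCitation, format: str = "text", site_config: SiteConfig | None = None) -> str:
    """Render a joint citation in one of ``text``, ``bibtex``, ``ris``, ``wikitext``."""
    cfg = site_config or SiteConfig()
    token = cfg.empty_contributors_token
    if format == "text":
        return render_text(citation, token)
    if format == "bibtex":
        return render_bibtex(citation, token)
    if format == "ris":
        return render_ris(citation, token)
    if format == "wikitext":
        return render_wikitext(citation, cfg)
    raise ValueError(f"unknown citation format {format!r}; expected one of {FORMATS}")
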