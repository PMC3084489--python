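"""MediaWiki XML export dumps: parsing and version-specific attribution.

Revision numbers (``oldid``) are site-wide: a single consecutive counter for
all revisions of all pages of one wiki, so a revision id alone pins one exact
page version.  Contributor attribution for a displayed version is the set of
users of that revision and of every earlier revision of the same page.
"""

from __future__ import annotations

import datetime as _dt
import logging
import os
import xml.etree.ElementTree as ET
from collections.abc import Iterable
from dataclasses import dataclass
from pathlib import Path

from taxonpages.config import SiteConfig
from taxonpages.errors import DumpParseError, RevisionLookupError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Revision:
    """One time-stamped, user-attributed edit of a wiki page."""

    rev_id: int
    timestamp: _dt.datetime
    user: str
    is_bot: bool = False
    comment: str = ""

    def __post_init__(self) -> None:
        if self.rev_id <= 0:
            raise ValidationError(f"rev_id must be positive, got {self.rev_id}")


@dataclass(frozen=True)
class PageHistory:
    title: str
    revisions: tuple[Revision, ...]

    def __post_init__(self) -> None:
        if not self.revisions:
            raise ValidationError(f"page {self.title!r} has no revisions")
        ids = [r.rev_id for r in self.revisions]
        if ids != sorted(ids) or len(ids) != len(set(ids)):
            raise ValidationError(f"page {self.title!r}: revision ids must be strictly ascending")
        stamps = [r.timestamp for r in self.revisions]
        if stamps != sorted(stamps):
            raise ValidationError(f"page {self.title!r}: timestamps must be non-decreasing")

    @property
    def latest(self) -> Revision:
        return self.revisions[-1]

    def revision(self, rev_id: int) -> Revision:
        for rev in self.revisions:
            if rev.rev_id == rev_id:
                return rev
        raise RevisionLookupError(f"revision {rev_id} not in history of {self.title!r}")


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _is_bot(username: str, bot_usernames: Iterable[str]) -> bool:
    # MediaWiki dumps carry no per-revision bot flag; bots are recognized by
    # the conventional "*bot" suffix or an explicit config list.
    return username in set(bot_usernames) or username.lower().endswith("bot")


def parse_export(
    xml_dump: str | bytes | os.PathLike,
    bot_usernames: Iterable[str] = (),
) -> list[PageHistory]:
    """Parse a standard MediaWiki XML export into page histories.

    Revisions found out of order are re-sorted ascending by id with a
    warning.  Duplicate revision ids anywhere in the dump violate site-wide
    numbering and raise :class:`ValidationError`.
    """
    if isinstance(xml_dump, os.PathLike) or (
        isinstance(xml_dump, str) and not xml_dump.lstrip().startswith("<")
    ):
        data = Path(xml_dump).read_bytes()
    elif isinstance(xml_dump, bytes):
        data = xml_dump
    else:
        data = xml_dump.encode("utf-8")
    try:
        root = ET.fromstring(data)
    except ET.ParseError as exc:
        line, col = exc.position
        raise DumpParseError(f"malformed dump at line {line}, column {col}: {exc.msg}") from exc
    if _localname(root.tag) != "mediawiki":
        raise DumpParseError(f"root element must be <mediawiki>, got <{_localname(root.tag)}>")

    histories: list[PageHistory] = []
    seen_ids: set[int] = set()
    for page_el in root:
        if _localname(page_el.tag) != "page":
            continue
        title = ""
        revisions: list[Revision] = []
        for child in page_el:
            name = _localname(child.tag)
            if name == "title":
                title = (child.text or "").strip()
            elif name == "revision":
                revisions.append(_parse_revision(child, bot_usernames))
        if not revisions:
            raise ValidationError(f"page {title!r} has no revisions")
        ordered = sorted(revisions, key=lambda r: r.rev_id)
        if ordered != revisions:
            logger.warning("page %r: revisions out of order in dump, re-sorted", title)
        for rev in ordered:
            if rev.rev_id in seen_ids:
                raise ValidationError(f"duplicate site-wide revision id {rev.rev_id}")
            seen_ids.add(rev.rev_id)
        histories.append(PageHistory(title=title, revisions=tuple(ordered)))
    return histories


def _parse_revision(rev_el: ET.Element, bot_usernames: Iterable[str]) -> Revision:
    rev_id: int | None = None
    timestamp: _dt.datetime | None = None
    user = ""
    comment = ""
    for child in rev_el:
        name = _localname(child.tag)
        if name == "id":
            rev_id = int((child.text or "").strip())
        elif name == "timestamp":
            text = (child.text or "").strip().replace("Z", "+00:00")
            timestamp = _dt.datetime.fromisoformat(text)
        elif name == "comment":
            comment = (child.text or "").strip()
        elif name == "contributor":
            for sub in child:
                if _localname(sub.tag) in ("username", "ip"):
                    user = (sub.text or "").strip()
    if rev_id is None or timestamp is None:
        raise DumpParseError("revision missing <id> or <timestamp>")
    if timestamp.tzinfo is None:
        timestamp = timestamp.replace(tzinfo=_dt.timezone.utc)
    return Revision(
        rev_id=rev_id,
        timestamp=timestamp.astimezone(_dt.timezone.utc),
        user=user,
        is_bot=_is_bot(user, bot_usernames),
        comment=comment,
    )


def contributors_at(history: PageHistory, rev_id: int, exclude_bots: bool = True) -> list[str]:
    """Contributors to the version ``rev_id`` of a page.

    Returns the deduplicated usernames of the revision itself and of all
    earlier revisions of the same page, sorted alphabetically
    (case-insensitive, case-sensitive tiebreak).  Anonymous editors appear as
    their IP string.

    Raises
    ------
    RevisionLookupError
        If ``rev_id`` is not a revision of this page.
    """
    history.revision(rev_id)  # raises if absent
    users = {
        rev.user
        for rev in history.revisions
        if rev.rev_id <= rev_id and rev.user and not (exclude_bots and rev.is_bot)
    }
    return sorted(users, key=lambda u: (u.casefold(), u))


def generic_url(site_config: SiteConfig, title: str) -> str:
    """URL that always resolves to the newest version of a page."""
    return f"{site_config.base_url}/wiki/{title}"


def permanent_url(site_config: SiteConfig, title: str, rev_id: int) -> str:
    """URL pinned to one numbered revision (``oldid``) of a page."""
    return (
        f"{site_config.base_url}{site_config.script_path}"
        f"/index.php?title={title}&oldid={rev_id}"
    )
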