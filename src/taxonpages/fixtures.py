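"""Deterministic synthetic test data: articles, wiki dumps, manifests.

Every generator is driven by a single integer seed; each internal choice
pulls from its own named pseudo-random stream, so extending one generator
never perturbs the output of another.  Regeneration with the same seed is
byte-identical.
"""

from __future__ import annotations

import datetime as _dt
import json
import random
import xml.etree.ElementTree as ET
from dataclasses import asdict, dataclass, field

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"

SECTION_LABEL_POOL = [
    "Type Location",
    "Description",
    "Distribution",
    "Etymology",
    "Diagnosis",
    "Ecology",
    "Remarks",
    "Materials examined",
]

_JOURNALS = ["ZooKeys", "PhytoKeys"]


def _stream(seed: int, name: str) -> random.Random:
    """A dedicated PRNG stream; string seeding is stable across runs."""
    return random.Random(f"{seed}:{name}")


def _word(rng: random.Random, n_syllables: int) -> str:
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n_syllables)
    )


def _sentence(rng: random.Random, n_words: int) -> str:
    words = [_word(rng, rng.randint(2, 4)) for _ in range(n_words)]
    return (" ".join(words)).capitalize() + "."


def _surname(rng: random.Random) -> str:
    return _word(rng, rng.randint(2, 3)).capitalize()


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreatmentManifest:
    taxon: str  # space-separated binomial
    authorship: str
    section_labels: tuple[str, ...]
    n_figures: int
    n_references: int
    figure_filenames: tuple[str, ...] = ()
    #: (n_couplets, n_leads) or None when the treatment carries no key.
    key_shape: tuple[int, int] | None = None


@dataclass(frozen=True)
class RevisionManifest:
    rev_id: int
    user: str
    timestamp: str  # ISO-8601 UTC, trailing Z
    is_bot: bool


@dataclass(frozen=True)
class HistoryManifest:
    title: str
    revisions: tuple[RevisionManifest, ...]


@dataclass(frozen=True)
class FixtureManifest:
    """Ground truth for one generated fixture file."""

    seed: int
    treatments: tuple[TreatmentManifest, ...] = ()
    histories: tuple[HistoryManifest, ...] = ()

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


# ---------------------------------------------------------------------------
# Article generator
# ---------------------------------------------------------------------------


def _sub(parent: ET.Element, tag: str, text: str = "", **attrs: str) -> ET.Element:
    el = ET.SubElement(parent, tag, {k: v for k, v in attrs.items() if v})
    if text:
        el.text = text
    return el


def _serialize(root: ET.Element) -> str:
    ET.indent(root)
    return '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(root, encoding="unicode") + "\n"


def generate_article(
    seed: int,
    n_treatments: int,
    sections_per_treatment: int | None = None,
) -> tuple[str, FixtureManifest]:
    """Generate one article document plus its ground-truth manifest.

    Taxon names are pronounceable nonsense, unique within the article.  When
    ``sections_per_treatment`` is None each treatment gets 2-4 sections drawn
    from a fixed label pool.  The first treatment carries a dichotomous key
    whenever the article has at least two treatments.
    """
    if n_treatments < 0:
        raise ValueError("n_treatments must be >= 0")
    names_rng = _stream(seed, "article:names")
    meta_rng = _stream(seed, "article:meta")
    body_rng = _stream(seed, "article:body")

    # Bibliographic metadata.
    year = meta_rng.randint(2008, 2011)
    n_authors = meta_rng.randint(2, 4)
    authors = []
    for _ in range(n_authors):
        initials = "".join(meta_rng.choice("ABDEGHKLMPRST") for _ in range(meta_rng.randint(1, 2)))
        authors.append(f"{_surname(meta_rng)} {initials}")
    journal = meta_rng.choice(_JOURNALS)
    issue = str(meta_rng.randint(10, 150))
    first_page = meta_rng.randint(1, 60)
    pages = f"{first_page}-{first_page + meta_rng.randint(5, 40)}"
    doi = f"10.3897/{journal.lower()}.{issue}.{meta_rng.randint(100, 9999)}"
    pub_date = _dt.date(year, meta_rng.randint(1, 12), meta_rng.randint(1, 28))

    # Unique taxon names.
    taxa: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(taxa) < n_treatments:
        name = (_word(names_rng, names_rng.randint(3, 4)).capitalize(),
                _word(names_rng, names_rng.randint(3, 4)))
        if name not in seen:
            seen.add(name)
            taxa.append(name)

    root = ET.Element("article")
    meta_el = ET.SubElement(root, "article-meta")
    _sub(meta_el, "title", f"A revision of the genus {taxa[0][0] if taxa else _word(meta_rng, 3).capitalize()}")
    _sub(meta_el, "journal", journal)
    _sub(meta_el, "issue", issue)
    _sub(meta_el, "pages", pages)
    _sub(meta_el, "doi", doi)
    _sub(meta_el, "year", str(year))
    _sub(meta_el, "pub-date", pub_date.isoformat())
    authors_el = ET.SubElement(meta_el, "authors")
    for a in authors:
        _sub(authors_el, "author", a)

    treatment_manifests: list[TreatmentManifest] = []
    for index, (genus, epithet) in enumerate(taxa):
        t_el = ET.SubElement(root, "treatment")
        taxon_el = ET.SubElement(t_el, "taxon", {"rank": "species"})
        _sub(taxon_el, "genus", genus)
        _sub(taxon_el, "species-epithet", epithet)
        authorship = f"{_surname(body_rng)} & {_surname(body_rng)}, {year}"
        _sub(taxon_el, "authorship", authorship)
        cls_el = ET.SubElement(taxon_el, "classification")
        _sub(cls_el, "rank", _word(body_rng, 3).capitalize() + "ida", name="ordo")
        _sub(cls_el, "rank", _word(body_rng, 3).capitalize() + "idae", name="familia")
        _sub(t_el, "zoobank-lsid",
             f"urn:lsid:zoobank.org:act:{body_rng.getrandbits(32):08X}")

        n_sections = (
            sections_per_treatment
            if sections_per_treatment is not None
            else body_rng.randint(2, 4)
        )
        n_sections = min(n_sections, len(SECTION_LABEL_POOL))
        labels = body_rng.sample(SECTION_LABEL_POOL, n_sections)
        for label in labels:
            s_el = ET.SubElement(t_el, "section", {"label": label})
            for _ in range(body_rng.randint(1, 2)):
                _sub(s_el, "p", _sentence(body_rng, body_rng.randint(6, 14)))
            if label == "Distribution":
                lat = f"{body_rng.uniform(-60, 60):.4f}"
                lon = f"{body_rng.uniform(-180, 180):.4f}"
                _sub(
                    s_el,
                    "coordinate",
                    f"{lat}, {lon}",
                    lat=lat,
                    lon=lon,
                    url=f"https://maps.example.org/?q={lat},{lon}",
                )

        key_shape: tuple[int, int] | None = None
        if index == 0 and n_treatments >= 2:
            n_couplets = min(3, n_treatments)
            key_el = ET.SubElement(t_el, "key")
            for c in range(1, n_couplets + 1):
                c_el = ET.SubElement(key_el, "couplet", {"number": str(c)})
                terminal = f"{taxa[c - 1][0]} {taxa[c - 1][1]}"
                if c < n_couplets:
                    _sub(c_el, "lead", _sentence(body_rng, 5), **{"to-couplet": str(c + 1)})
                else:
                    _sub(c_el, "lead", _sentence(body_rng, 5),
                         taxon=f"{taxa[n_couplets % n_treatments][0]} {taxa[n_couplets % n_treatments][1]}")
                _sub(c_el, "lead", _sentence(body_rng, 5), taxon=terminal)
            key_shape = (n_couplets, 2 * n_couplets)

        n_figures = body_rng.randint(0, 2)
        figure_filenames = []
        for f in range(1, n_figures + 1):
            filename = f"{genus.lower()}_{epithet}_{f}.jpg"
            figure_filenames.append(filename)
            fig_el = ET.SubElement(t_el, "figure", {"id": f"F{f}", "filename": filename})
            _sub(fig_el, "caption", _sentence(body_rng, body_rng.randint(5, 10)))

        n_references = body_rng.randint(1, 3)
        refs_el = ET.SubElement(t_el, "references")
        for _ in range(n_references):
            ref_year = body_rng.randint(1900, year)
            _sub(
                refs_el,
                "ref",
                f"{_surname(body_rng)} {body_rng.choice('ABDEGH')} ({ref_year}) "
                f"{_sentence(body_rng, 5)} {body_rng.choice(_JOURNALS)} "
                f"{body_rng.randint(1, 99)}: {body_rng.randint(1, 400)}.",
            )

        treatment_manifests.append(
            TreatmentManifest(
                taxon=f"{genus} {epithet}",
                authorship=authorship,
                section_labels=tuple(labels),
                n_figures=n_figures,
                n_references=n_references,
                figure_filenames=tuple(figure_filenames),
                key_shape=key_shape,
            )
        )

    manifest = FixtureManifest(seed=seed, treatments=tuple(treatment_manifests))
    return _serialize(root), manifest


# ---------------------------------------------------------------------------
# History generator
# ---------------------------------------------------------------------------

_MW_NS = "http://www.mediawiki.org/xml/export-0.10/"
_EPOCH = _dt.datetime(2011, 1, 1, tzinfo=_dt.timezone.utc)


def generate_history(
    seed: int,
    n_pages: int,
    n_revisions: int,
    n_users: int = 5,
    bot_fraction: float = 0.2,
) -> tuple[str, FixtureManifest]:
    """Generate a MediaWiki XML export dump plus its manifest.

    Revision ids are site-wide: one strictly increasing counter shared by
    all pages, assigned round-robin first (guaranteeing every page at least
    one revision and interleaved ids), then randomly.  Timestamps increase
    strictly with rev_id.
    """
    if n_pages < 1:
        raise ValueError("n_pages must be >= 1")
    if n_revisions < n_pages:
        raise ValueError("n_revisions must be >= n_pages")

    names_rng = _stream(seed, "history:names")
    users_rng = _stream(seed, "history:users")
    revs_rng = _stream(seed, "history:revisions")

    titles: list[str] = []
    seen: set[str] = set()
    while len(titles) < n_pages:
        title = (
            _word(names_rng, names_rng.randint(3, 4)).capitalize()
            + "_"
            + _word(names_rng, names_rng.randint(3, 4))
        )
        if title not in seen:
            seen.add(title)
            titles.append(title)

    n_bots = round(bot_fraction * n_users)
    users = [_word(users_rng, users_rng.randint(2, 3)).capitalize() + "Bot" for _ in range(n_bots)]
    users += [_word(users_rng, users_rng.randint(2, 3)).capitalize() for _ in range(n_users - n_bots)]

    # Site-wide numbering with gaps, interleaved across pages.
    rev_id = 100
    minute = 0
    assignments: dict[str, list[RevisionManifest]] = {t: [] for t in titles}
    for i in range(n_revisions):
        rev_id += revs_rng.randint(1, 3)
        minute += revs_rng.randint(1, 120)
        title = titles[i % n_pages] if i < n_pages else revs_rng.choice(titles)
        user = revs_rng.choice(users)
        stamp = (_EPOCH + _dt.timedelta(minutes=minute)).strftime("%Y-%m-%dT%H:%M:%SZ")
        assignments[title].append(
            RevisionManifest(
                rev_id=rev_id,
                user=user,
                timestamp=stamp,
                is_bot=user.endswith("Bot"),
            )
        )

    ET.register_namespace("", _MW_NS)
    root = ET.Element(f"{{{_MW_NS}}}mediawiki", {"version": "0.10"})
    for page_id, title in enumerate(titles, start=1):
        page_el = ET.SubElement(root, f"{{{_MW_NS}}}page")
        _sub(page_el, f"{{{_MW_NS}}}title", title)
        _sub(page_el, f"{{{_MW_NS}}}ns", "0")
        _sub(page_el, f"{{{_MW_NS}}}id", str(page_id))
        for k, rev in enumerate(assignments[title]):
            rev_el = ET.SubElement(page_el, f"{{{_MW_NS}}}revision")
            _sub(rev_el, f"{{{_MW_NS}}}id", str(rev.rev_id))
            _sub(rev_el, f"{{{_MW_NS}}}timestamp", rev.timestamp)
            contrib_el = ET.SubElement(rev_el, f"{{{_MW_NS}}}contributor")
            _sub(contrib_el, f"{{{_MW_NS}}}username", rev.user)
            _sub(rev_el, f"{{{_MW_NS}}}comment", f"edit {k + 1}")
            _sub(rev_el, f"{{{_MW_NS}}}text", f"Content of {title}, revision {rev.rev_id}.")

    manifest = FixtureManifest(
        seed=seed,
        histories=tuple(
            HistoryManifest(title=t, revisions=tuple(assignments[t])) for t in titles
        ),
    )
    return _serialize(root), manifest
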