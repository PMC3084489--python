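import datetime as dt
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from taxonpages.config import SiteConfig
from taxonpages.fixtures import generate_article, generate_history
from taxonpages.revision_history import PageHistory, Revision
from taxonpages.taxpub_reader import ArticleMeta, parse_article

EXAMPLES = Path(__file__).resolve().parents[1] / "examples"

MINIMAL_ARTICLE = """<?xml version="1.0" encoding="UTF-8"?>
<article>
  <article-meta>
    <title>A tiny paper</title>
    <journal>ZooKeys</journal>
    <issue>90</issue>
    <pages>1-5</pages>
    <doi>10.3897/zookeys.90.1000</doi>
    <year>2011</year>
    <pub-date>2011-04-14</pub-date>
    <authors><author>Stoev P</author><author>Enghoff H</author></authors>
  </article-meta>
  <treatment>
    <taxon rank="species">
      <genus>Sinocallipus</genus>
      <species-epithet>catba</species-epithet>
      <authorship>Stoev &amp; Enghoff, 2011</authorship>
    </taxon>
    <section label="Description"><p>A pale cave millipede.</p></section>
  </treatment>
</article>
"""


@pytest.fixture(scope="session")
def cfg():
    return SiteConfig()


@pytest.fixture(scope="session")
def article3():
    """(parsed article, manifest, raw xml) for the 3-treatment fixture."""
    xml, manifest = generate_article(seed=1, n_treatments=3)
    return parse_article(xml), manifest, xml


@pytest.fixture(scope="session")
def dump10():
    """(histories, manifest, raw xml) for a 2-page, 10-revision dump."""
    from taxonpages.revision_history import parse_export

    xml, manifest = generate_history(seed=7, n_pages=2, n_revisions=10)
    return parse_export(xml), manifest, xml


@pytest.fixture
def minimal_article():
    return parse_article(MINIMAL_ARTICLE)


@pytest.fixture
def sample_meta():
    return ArticleMeta(
        authors=("Stoev P", "Enghoff H"),
        year=2011,
        title="A tiny paper",
        journal="ZooKeys",
        issue_no="90",
        pages="1-5",
        doi="10.3897/zookeys.90.1000",
        publication_date=dt.date(2011, 4, 14),
    )


def make_history(title="Sinocallipus_catba", revs=((101, "Alice", False), (105, "Bob", False), (109, "Alice", False))):
    base = dt.datetime(2011, 4, 14, 12, 0, tzinfo=dt.timezone.utc)
    return PageHistory(
        title=title,
        revisions=tuple(
            Revision(
                rev_id=rid,
                timestamp=base + dt.timedelta(minutes=i),
                user=user,
                is_bot=is_bot,
            )
            for i, (rid, user, is_bot) in enumerate(revs)
        ),
    )


@pytest.fixture
def abc_history():
    return make_history()
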