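"""Independent oracles used by the tests.

Everything here is deliberately implemented without calling into the package
so that each check has two independent routes: the implementation under test
and a brute-force or hand-rolled reference.
"""

from __future__ import annotations

import re

# Single-reference grammar of the canonical text citation:
#   <authors> (<year>) <rest of journal half>. Versioned wiki page:
#   <YYYY-MM-DD>, version <rev>, <url>, contributors (alphabetical order):
#   <names>.
CITATION_GRAMMAR = re.compile(
    r"^(?P<authors>.+?) "
    r"\((?P<year>\d{4})\) "
    r"(?P<journal_half>.+?)\. "
    r"Versioned wiki page: "
    r"(?P<date>\d{4}-\d{2}-\d{2}), "
    r"version (?P<rev>\d+), "
    r"(?P<url>\S+), "
    r"contributors \(alphabetical order\): "
    r"(?P<contributors>.+)\.$"
)


def brute_force_contributors(revisions, rev_id, exclude_bots=True):
    """Prefix-union attribution oracle over (rev_id, user, is_bot) triples."""
    users = set()
    for rid, user, is_bot in revisions:
        if rid <= rev_id and user and not (exclude_bots and is_bot):
            users.add(user)
    return sorted(users, key=lambda u: (u.casefold(), u))


def count_balance(markup: str) -> dict[str, int]:
    """Token-count balance check, independent of the package's stack checker."""
    visible = re.sub(r"<nowiki>.*?</nowiki>", "", markup, flags=re.DOTALL)
    return {
        "open_tpl": visible.count("{{"),
        "close_tpl": visible.count("}}"),
        "open_link": visible.count("[["),
        "close_link": visible.count("]]"),
    }


def assert_balanced(markup: str) -> None:
    counts = count_balance(markup)
    assert counts["open_tpl"] == counts["close_tpl"], counts
    assert counts["open_link"] == counts["close_link"], counts


def parse_bibtex(text: str) -> tuple[str, str, dict[str, str]]:
    """Minimal brace-aware BibTeX parser: returns (entry type, key, fields)."""
    text = text.strip()
    m = re.match(r"@(\w+)\{([^,]+),", text)
    assert m, f"no BibTeX entry header in {text[:60]!r}"
    entry_type, key = m.group(1), m.group(2)
    fields: dict[str, str] = {}
    i = m.end()
    while i < len(text):
        fm = re.compile(r"\s*(\w+)\s*=\s*\{").match(text, i)
        if not fm:
            break
        name = fm.group(1)
        depth = 1
        j = fm.end()
        while j < len(text) and depth:
            if text[j] == "{":
                depth += 1
            elif text[j] == "}":
                depth -= 1
            j += 1
        fields[name] = text[fm.end() : j - 1]
        i = j
        while i < len(text) and text[i] in ",\n ":
            i += 1
    return entry_type, key, fields


def parse_ris(text: str) -> list[tuple[str, str]]:
    """Parse RIS tag lines into ordered (tag, value) pairs."""
    pairs = []
    for line in text.splitlines():
        if not line.strip():
            continue
        assert re.match(r"^[A-Z][A-Z0-9]  - ", line), f"bad RIS line {line!r}"
        pairs.append((line[:2], line[6:]))
    return pairs
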