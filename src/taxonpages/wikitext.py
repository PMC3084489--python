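"""Small wikitext utilities: escaping, template serialization, balance checks.

These are deliberately minimal — the emitter only needs to *write* safe
markup, not to parse arbitrary wikitext.
"""

from __future__ import annotations

import re

# Tokens that can break templates or links when they occur in content text.
_SPECIAL = re.compile(r"(\{\{|\}\}|\[\[|\]\]|\|)")

_NOWIKI_SPAN = re.compile(r"<nowiki>.*?</nowiki>", re.DOTALL)


def escape(text: str) -> str:
    """Wrap wiki-special tokens in ``<nowiki>`` spans.

    Applied to all content text placed inside markup the emitter generates,
    so user content can never unbalance a template or a link.
    """
    return _SPECIAL.sub(lambda m: f"<nowiki>{m.group(1)}</nowiki>", text)


def serialize_template(name: str, params: list[tuple[str, str]]) -> str:
    """Render a template call with one ``|key=value`` per line."""
    if not params:
        return "{{" + name + "}}"
    lines = ["{{" + name]
    for key, value in params:
        lines.append(f"|{key}={value}")
    lines.append("}}")
    return "\n".join(lines)


def check_balanced(markup: str) -> list[str]:
    """Return a list of balance problems ('' means none) in the markup.

    Checks that ``{{``/``}}`` and ``[[``/``]]`` pairs nest properly outside
    ``<nowiki>`` spans.  Returns an empty list when the markup is clean.
    """
    problems: list[str] = []
    visible = _NOWIKI_SPAN.sub("", markup)
    stack: list[str] = []
    i = 0
    n = len(visible)
    while i < n:
        two = visible[i : i + 2]
        if two in ("{{", "[["):
            stack.append(two)
            i += 2
        elif two == "}}":
            if not stack or stack[-1] != "{{":
                problems.append(f"unmatched '}}}}' at offset {i}")
            else:
                stack.pop()
            i += 2
        elif two == "]]":
            if not stack or stack[-1] != "[[":
                problems.append(f"unmatched ']]' at offset {i}")
            else:
                stack.pop()
            i += 2
        else:
            i += 1
    for opener in stack:
        problems.append(f"unclosed '{opener}'")
    return problems
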