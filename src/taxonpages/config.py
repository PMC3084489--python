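"""Site configuration: URL layout, template names, external-resource registry.

Configuration is one YAML file; every key has a default so the package works
with no config at all.  The default external-resource registry covers the
twelve biodiversity resources the link hub targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

#: Default external-resource registry: (resource name, URL template).
#: Each template contains exactly one ``{name}`` placeholder that receives
#: the percent-encoded binomial.
DEFAULT_RESOURCES: list[tuple[str, str]] = [
    ("GBIF", "https://www.gbif.org/species/search?q={name}"),
    ("EOL", "https://eol.org/search?q={name}"),
    ("NCBI", "https://www.ncbi.nlm.nih.gov/taxonomy/?term={name}"),
    ("PubMed", "https://pubmed.ncbi.nlm.nih.gov/?term={name}"),
    ("BHL", "https://www.biodiversitylibrary.org/name/{name}"),
    ("ZooBank", "http://zoobank.org/Search?search_term={name}"),
    ("IPNI", "https://www.ipni.org/search?q={name}"),
    ("Index Fungorum", "http://www.indexfungorum.org/names/Names.asp?strGenus={name}"),
    ("Tropicos", "https://www.tropicos.org/name/Search?name={name}"),
    ("PLANTS", "https://plants.usda.gov/home/nameSearch?keywordsearch={name}"),
    ("Wikispecies", "https://species.wikimedia.org/wiki/{name}"),
    ("Wikipedia", "https://en.wikipedia.org/wiki/{name}"),
]

DEFAULT_TEMPLATES: dict[str, str] = {
    "citation": "Cite treatment",
    "classification": "Taxonomy",
    "external_links": "External links",
    "cite_wiki": "Cite",
}


@dataclass(frozen=True)
class SiteConfig:
    """URL layout and emission policy of the target wiki site."""

    base_url: str = "http://species-id.net"
    #: Script path of index.php; the generic article path is always "/wiki".
    script_path: str = "/w"
    templates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    resources: list[tuple[str, str]] = field(
        default_factory=lambda: list(DEFAULT_RESOURCES)
    )
    #: Drop bot accounts from contributor lists in citations.
    exclude_bots: bool = True
    #: Usernames treated as bots in addition to the "*bot" suffix convention.
    bot_usernames: frozenset[str] = frozenset()
    #: Token rendered when the contributor list is empty.
    empty_contributors_token: str = "none"
    #: When true, title collisions get an "_(Author_Year)" suffix instead of
    #: raising an error.
    disambiguate_titles: bool = False

    def template(self, role: str) -> str:
        return self.templates.get(role, DEFAULT_TEMPLATES[role])


def load_config(path: str | Path | None = None, **overrides: object) -> SiteConfig:
    """Load a :class:`SiteConfig` from YAML, applying keyword overrides.

    Unknown YAML keys are rejected so typos surface immediately.
    """
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    known = set(SiteConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")

    if "resources" in data:
        entries = []
        for item in data["resources"]:
            if isinstance(item, dict):
                entries.append((str(item["name"]), str(item["url"])))
            else:
                name, url = item
                entries.append((str(name), str(url)))
        data["resources"] = entries
    if "templates" in data:
        merged = dict(DEFAULT_TEMPLATES)
        merged.update({str(k): str(v) for k, v in data["templates"].items()})
        data["templates"] = merged
    if "bot_usernames" in data:
        data["bot_usernames"] = frozenset(str(u) for u in data["bot_usernames"])

    cfg = SiteConfig(**data)
    if cfg.base_url.endswith("/"):
        cfg = replace(cfg, base_url=cfg.base_url.rstrip("/"))
    return cfg
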