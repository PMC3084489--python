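# taxonpages

A journal-to-wiki publishing bridge for taxonomic literature. The package

1. parses structured taxonomic journal articles (a pinned subset of
   TaxPub/NLM-style XML, defined in `schemas/taxpub_subset.rnc`) into a
   domain model of articles and taxon treatments;
2. converts every treatment into a MediaWiki page — citation and
   classification templates, level-2 section headings in source order,
   dichotomous keys as wiki tables, figures, reference lists, and a hub of
   links to twelve external biodiversity resources — plus an inert upload
   plan (no network access anywhere);
3. parses standard MediaWiki XML export dumps and computes version-specific
   attribution: the contributor list of any revision is the alphabetical
   union of all users of that revision and every earlier revision of the
   page (site-wide `oldid` numbering, generic vs. permanent URLs);
4. builds the combined journal + versioned-wiki citation and renders it as
   plain text, BibTeX, RIS, or a wikitext cite-template call.

A deterministic fixtures module generates synthetic articles and revision
dumps with ground-truth manifests, so everything is testable offline.

## CLI

```bash
# Convert an article into per-treatment .wiki files + manifest + upload plan
taxonpages convert examples/sinocallipus.xml -o out/ [--config examples/config.yaml]

# Per-treatment generic wiki URLs, for insertion into the journal source
taxonpages backlink examples/sinocallipus.xml

# Joint journal+wiki citation for one page revision of a dump
taxonpages cite examples/generated_dump_seed7.xml \
    --page Toracece_bemibuti --rev latest --format text \
    --article examples/generated_article_seed42.xml

# Deterministic synthetic data
taxonpages fixtures article --seed 1 --treatments 3 -o article.xml --manifest m.json
taxonpages fixtures history --seed 7 --pages 2 --revisions 10 -o dump.xml
```

Exit codes: 0 success, 1 parse/validation failure, 2 usage error. Data goes
to stdout, logging to stderr.

Citation text form:

```
<authors> (<year>) <title> <journal> <issue> <pages> <doi>. Versioned wiki
page: <YYYY-MM-DD>, version <rev>, <permanent url>, contributors
(alphabetical order): <names>.
```

## Configuration

One YAML file (see `examples/config.yaml`): site base URL, `index.php`
script path, template names, the external-resource registry (URL templates
with a `{name}` placeholder), bot handling, and the title-collision policy.
Defaults target `http://species-id.net` with script path `/w`.

## Layout

```
src/taxonpages/
  taxpub_reader.py    article XML -> domain model
  wiki_emitter.py     treatments -> wiki pages, keys, external links
  revision_history.py dump parsing, contributors_at, generic/permanent URLs
  citation.py         joint citations + text/BibTeX/RIS/wikitext renderers
  fixtures.py         deterministic synthetic articles & dumps + manifests
  config.py, wikitext.py, errors.py, cli.py
schemas/taxpub_subset.rnc   supported XML vocabulary (RELAX NG compact)
examples/                   example articles, dump, config
```
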