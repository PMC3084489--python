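import urllib.parse

import pytest

from taxonpages.config import SiteConfig
from taxonpages.errors import TitleCollisionError, ValidationError
from taxonpages.taxpub_reader import (
    IdentificationKey,
    KeyCouplet,
    KeyLead,
    TaxonName,
    Treatment,
    parse_article,
)
from taxonpages.wiki_emitter import (
    ResourceRegistry,
    emit_article,
    emit_key,
    emit_page,
    external_links,
    page_title,
)
from taxonpages.wikitext import check_balanced

from conftest import MINIMAL_ARTICLE
from oracles import assert_balanced


class TestPageTitle:
    @pytest.mark.parametrize(
        "genus,epithet,expected",
        [
            ("Sinocallipus", "catba", "Sinocallipus_catba"),
            ("Neobidessodes", "darwiniensis", "Neobidessodes_darwiniensis"),
            ("Anochetus", "boltoni", "Anochetus_boltoni"),
        ],
    )
    def test_worked_examples(self, genus, epithet, expected):
        assert page_title(TaxonName(genus=genus, species_epithet=epithet)) == expected

    def test_infraspecific_appended(self):
        name = TaxonName(genus="Apis", species_epithet="mellifera",
                         infraspecific_epithet="ligustica", rank="subspecies")
        assert page_title(name) == "Apis_mellifera_ligustica"

    def test_genus_only(self):
        assert page_title(TaxonName(genus="Sinocallipus", rank="genus")) == "Sinocallipus"


class TestEmitPage:
    def test_section_heading_order(self, article3, cfg):
        article, manifest, _ = article3
        for treatment, truth in zip(article.treatments, manifest.treatments):
            page = emit_page(treatment, article.meta, site_config=cfg)
            positions = [page.markup.index(f"== {label} ==") for label in truth.section_labels]
            assert positions == sorted(positions)

    def test_description_before_distribution(self):
        xml = MINIMAL_ARTICLE.replace(
            '<section label="Description"><p>A pale cave millipede.</p></section>',
            '<section label="Description"><p>a</p></section>'
            '<section label="Distribution"><p>b</p></section>',
        )
        article = parse_article(xml)
        page = emit_page(article.treatments[0], article.meta)
        assert page.markup.index("== Description ==") < page.markup.index("== Distribution ==")

    def test_zero_sections_structural_minimum(self, sample_meta, cfg):
        treatment = Treatment(taxon=TaxonName(genus="Sinocallipus", species_epithet="catba"))
        page = emit_page(treatment, sample_meta, site_config=cfg)
        assert page.markup.lstrip().startswith("{{" + cfg.template("citation"))
        assert "{{" + cfg.template("classification") in page.markup
        assert "{{" + cfg.template("external_links") in page.markup

    def test_citation_template_is_first_construct(self, article3, cfg):
        article, _, _ = article3
        for page in emit_article(article, site_config=cfg):
            assert page.markup.lstrip().startswith("{{" + cfg.template("citation"))

    def test_two_figures_named_and_listed(self, article3):
        article, manifest, _ = article3
        pairs = [
            (t, m) for t, m in zip(article.treatments, manifest.treatments) if m.n_figures == 2
        ]
        if not pairs:  # fall back to a hand-built treatment
            pytest.skip("seed produced no 2-figure treatment")
        treatment, truth = pairs[0]
        page = emit_page(treatment, article.meta)
        assert len(page.images) == 2
        title = page.title
        for i, (source, wiki_name) in enumerate(page.images, start=1):
            assert source == truth.figure_filenames[i - 1]
            assert wiki_name == f"{title}_fig{i}.jpg"
            assert f"[[File:{wiki_name}|" in page.markup

    def test_doi_present_in_citation_template(self, article3, cfg):
        article, _, _ = article3
        for page in emit_article(article, site_config=cfg):
            assert f"|doi={article.meta.doi}" in page.markup

    def test_zoobank_lsid_rendered_as_external_link(self, minimal_article):
        xml = MINIMAL_ARTICLE.replace(
            "</taxon>",
            "</taxon><zoobank-lsid>urn:lsid:zoobank.org:act:TEST</zoobank-lsid>",
        )
        article = parse_article(xml)
        page = emit_page(article.treatments[0], article.meta)
        assert "[http://zoobank.org/urn:lsid:zoobank.org:act:TEST" in page.markup

    def test_special_characters_escaped(self, sample_meta):
        from taxonpages.taxpub_reader import Block, BlockKind, TreatmentSection

        hostile = TreatmentSection(
            label="Remarks",
            blocks=(Block(BlockKind.PARAGRAPH, text="breaks | [[stuff]] and {{templates}}"),),
        )
        treatment = Treatment(
            taxon=TaxonName(genus="Evil", species_epithet="pipe"), sections=(hostile,)
        )
        page = emit_page(treatment, sample_meta)
        assert not check_balanced(page.markup)
        assert_balanced(page.markup)
        assert "<nowiki>|</nowiki>" in page.markup

    def test_markup_balanced_on_fixtures(self, article3):
        article, _, _ = article3
        for page in emit_article(article):
            assert check_balanced(page.markup) == []
            assert_balanced(page.markup)

    def test_determinism(self, article3):
        article, _, _ = article3
        first = [p.markup for p in emit_article(article)]
        second = [p.markup for p in emit_article(article)]
        assert first == second


class TestEmitArticle:
    def test_one_page_per_treatment(self, article3):
        article, _, _ = article3
        assert len(emit_article(article)) == len(article.treatments)

    def test_title_collision_raises(self, sample_meta):
        from taxonpages.taxpub_reader import TaxPubArticle

        taxon = TaxonName(genus="Sinocallipus", species_epithet="catba", authorship="Stoev, 2011")
        article = TaxPubArticle(
            meta=sample_meta,
            treatments=(Treatment(taxon=taxon), Treatment(taxon=taxon)),
        )
        with pytest.raises(TitleCollisionError, match="Sinocallipus_catba"):
            emit_article(article)

    def test_title_collision_suffix_policy(self, sample_meta):
        from taxonpages.taxpub_reader import TaxPubArticle

        taxon = TaxonName(genus="Sinocallipus", species_epithet="catba", authorship="Stoev, 2011")
        article = TaxPubArticle(
            meta=sample_meta,
            treatments=(Treatment(taxon=taxon), Treatment(taxon=taxon)),
        )
        cfg = SiteConfig(disambiguate_titles=True)
        titles = [p.title for p in emit_article(article, site_config=cfg)]
        assert titles[0] == "Sinocallipus_catba"
        assert titles[1].startswith("Sinocallipus_catba_(")
        assert len(set(titles)) == 2

    def test_generic_url_backlink_property(self, article3, cfg):
        from taxonpages.wiki_emitter import backlink_urls

        article, _, _ = article3
        for (name, url), page in zip(backlink_urls(article, cfg), emit_article(article)):
            assert url == f"{cfg.base_url}/wiki/{page.title}"


class TestEmitKey:
    def test_smallest_valid_key(self):
        key = IdentificationKey(
            couplets=(
                KeyCouplet(
                    number=1,
                    leads=(
                        KeyLead(text="winged", taxon="Aus bus"),
                        KeyLead(text="wingless", taxon="Aus cus"),
                    ),
                ),
            )
        )
        table = emit_key(key)
        rows = [line for line in table.splitlines() if line.startswith("| ")]
        assert len(rows) == 2
        assert "[[Aus_bus|" in table and "[[Aus_cus|" in table

    def test_fixture_key_row_count(self, article3):
        article, manifest, _ = article3
        for treatment, truth in zip(article.treatments, manifest.treatments):
            if not truth.key_shape:
                continue
            _, n_leads = truth.key_shape
            table = emit_key(treatment.keys[0])
            rows = [line for line in table.splitlines() if line.startswith("| ")]
            assert len(rows) == n_leads

    def test_dangling_couplet_rejected_at_construction(self):
        with pytest.raises(ValidationError, match="missing couplet 5"):
            IdentificationKey(
                couplets=(
                    KeyCouplet(number=1, leads=(KeyLead(text="a", taxon="Aus bus"),)),
                    KeyCouplet(number=2, leads=(KeyLead(text="b", next_couplet=5),)),
                )
            )

    def test_emit_key_revalidates(self):
        # Bypass __post_init__ to exercise emit_key's own validation path.
        key = object.__new__(IdentificationKey)
        object.__setattr__(
            key,
            "couplets",
            (KeyCouplet(number=2, leads=(KeyLead(text="b", next_couplet=5),)),),
        )
        with pytest.raises(ValidationError, match="missing couplet 5"):
            emit_key(key)

    def test_next_couplet_rendered_as_anchor(self):
        key = IdentificationKey(
            couplets=(
                KeyCouplet(number=1, leads=(
                    KeyLead(text="go on", next_couplet=2),
                    KeyLead(text="stop", taxon="Aus bus"),
                )),
                KeyCouplet(number=2, leads=(KeyLead(text="end", taxon="Aus cus"),)),
            )
        )
        table = emit_key(key)
        assert "[[#couplet-2|2]]" in table
        assert 'id="couplet-2"' in table


class TestExternalLinks:
    def test_empty_registry(self):
        links = external_links(
            TaxonName(genus="Aus", species_epithet="bus"), ResourceRegistry(entries=())
        )
        assert links == []

    def test_default_registry_has_12_resources(self, cfg):
        registry = ResourceRegistry.from_config(cfg)
        links = external_links(TaxonName(genus="Aus", species_epithet="bus"), registry)
        assert len(links) == 12
        assert [name for name, _ in links] == [name for name, _ in registry.entries]

    def test_space_percent_encoded(self, cfg):
        taxon = TaxonName(genus="Sinocallipus", species_epithet="catba")
        reference = urllib.parse.quote("Sinocallipus catba", safe="")
        assert "%20" in reference
        for _, url in external_links(taxon, ResourceRegistry.from_config(cfg)):
            assert reference in url
            assert " " not in url

    def test_bad_registry_template_rejected(self):
        with pytest.raises(ValidationError, match="placeholder"):
            ResourceRegistry(entries=(("Broken", "https://x.org/{name}/{name}"),))
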