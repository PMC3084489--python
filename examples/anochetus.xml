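<?xml version="1.0" encoding="UTF-8"?>
<article>
  <article-meta>
    <title>A new species of the Anochetus madagascarensis group from the Seychelles</title>
    <journal>Zootaxa</journal>
    <issue>1767</issue>
    <pages>55-64</pages>
    <year>2008</year>
    <authors>
      <author>Fisher B</author>
    </authors>
  </article-meta>
  <treatment>
    <taxon rank="species">
      <genus>Anochetus</genus>
      <species-epithet>boltoni</species-epithet>
      <authorship>Fisher, 2008</authorship>
      <classification>
        <rank name="ordo">Hymenoptera</rank>
        <rank name="familia">Formicidae</rank>
      </classification>
    </taxon>
    <section label="Diagnosis">
      <p>Worker with linear mandibles and a strongly constricted petiole node.</p>
    </section>
    <section label="Description">
      <p>Head broader than long, eyes large; sculpture finely striate.</p>
    </section>
    <section label="Distribution">
      <p>Seychelles archipelago.</p>
    </section>
    <references>
      <ref>Brown W (1978) Contributions toward a reclassification of the Formicidae. Studia Entomologica 20: 549-638.</ref>
    </references>
  </treatment>
</article>
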