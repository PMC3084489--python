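<?xml version="1.0" encoding="UTF-8"?>
<article>
  <article-meta>
    <title>A review of the millipede genus Sinocallipus, with notes on gonopods monotony vs. peripheral diversity in callipodidans</title>
    <journal>ZooKeys</journal>
    <issue>90</issue>
    <pages>13-34</pages>
    <doi>10.3897/zookeys.90.1291</doi>
    <year>2011</year>
    <pub-date>2011-04-14</pub-date>
    <authors>
      <author>Stoev P</author>
      <author>Enghoff H</author>
    </authors>
  </article-meta>
  <treatment>
    <taxon rank="species">
      <genus>Sinocallipus</genus>
      <species-epithet>catba</species-epithet>
      <authorship>Stoev &amp; Enghoff, 2011</authorship>
      <classification>
        <rank name="ordo">Callipodida</rank>
        <rank name="familia">Sinocallipodidae</rank>
      </classification>
    </taxon>
    <zoobank-lsid>urn:lsid:zoobank.org:act:3B35CB2A-E09B-4388-BF05-1E586B9B49E2</zoobank-lsid>
    <section label="Type Location">
      <p>Vietnam, Hai Phong Province, Cat Ba Island, Cat Ba National Park, in a cave.</p>
      <coordinate lat="20.7980" lon="107.0481" url="https://maps.example.org/?q=20.7980,107.0481">20°47'N 107°02'E</coordinate>
    </section>
    <section label="Description">
      <p>A pale, long-legged callipodidan with reduced ocularia, adults with around 50 podous rings.</p>
      <fig-ref rid="F1">Fig. 1</fig-ref>
    </section>
    <section label="Distribution">
      <p>Known only from caves on Cat Ba Island, northern Vietnam.</p>
    </section>
    <section label="Etymology">
      <p>Named after the type locality, Cat Ba Island; a noun in apposition.</p>
    </section>
    <figure id="F1" filename="sinocallipus_catba_habitus.jpg">
      <caption>Habitus of the holotype, lateral view.</caption>
    </figure>
    <references>
      <ref>Hoffman R (1980) Classification of the Diplopoda. Museum d'Histoire Naturelle, Geneva, 237 pp.</ref>
      <ref>Zhang C (1993) On the cave-dwelling callipodid millipedes of China. Acta Zootaxonomica Sinica 18: 11-18.</ref>
    </references>
  </treatment>
</article>
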