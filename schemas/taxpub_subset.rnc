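# Supported article XML subset (RELAX NG compact syntax).
#
# This grammar is the normative definition of the element vocabulary the
# reader accepts.  Elements outside this subset are flattened to opaque
# paragraph text with a logged warning, never silently dropped.

start = article

article = element article { article-meta, treatment* }

article-meta = element article-meta {
  element title { text },
  element journal { text },
  element issue { text }?,
  element pages { text }?,
  element doi { text }?,        # must begin "10." when present
  element year { xsd:integer }?,  # defaults to the pub-date year
  element pub-date { xsd:date }?,
  element authors { element author { text }+ }
}

treatment = element treatment {
  taxon,
  element zoobank-lsid { text }?,
  (section | key | figure | references)*
}

taxon = element taxon {
  attribute rank { "genus" | "species" | "subspecies" }?,
  element genus { text },
  element species-epithet { text }?,
  element infraspecific-epithet { text }?,
  element authorship { text }?,
  element classification {
    element rank { attribute name { text }, text }*
  }?
}

section = element section {
  attribute label { text },
  (element p { text }
   | element fig-ref { attribute rid { text }, text? }
   | element coordinate {
       attribute lat { text }?, attribute lon { text }?,
       attribute url { text }?, text?
     }
   | element ext-id {
       attribute type { text }?, attribute url { text }?, text?
     })*
}

key = element key {
  element couplet {
    attribute number { xsd:integer },
    element lead {
      (attribute to-couplet { xsd:integer }
       | attribute taxon { text }),   # exactly one outcome per lead
      text
    }+
  }+
}

figure = element figure {
  attribute id { text }?,
  attribute filename { text },
  element caption { text }?
}

references = element references { element ref { text }* }
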