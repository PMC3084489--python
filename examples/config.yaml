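# Example site configuration. Every key is optional; defaults target
# http://species-id.net with script path /w.
base_url: http://species-id.net
script_path: /w
exclude_bots: true
empty_contributors_token: none
disambiguate_titles: false
bot_usernames:
  - ImportTool
templates:
  citation: Cite treatment
  classification: Taxonomy
  external_links: External links
  cite_wiki: Cite
# Uncomment to replace the default 12-resource registry:
# resources:
#   - name: GBIF
#     url: "https://www.gbif.org/species/search?q={name}"
#   - name: Wikispecies
#     url: "https://species.wikimedia.org/wiki/{name}"
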