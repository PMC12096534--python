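# Most recent references that mention two entities together, with
# optional restriction to review articles and/or PMC-available articles.
$prefixes

SELECT ?ref ?date ?journal ?title ?pmcid
WHERE {
  ?ref vocab:discussesAsDerivedByTextMining $entity_a .
  ?ref vocab:discussesAsDerivedByTextMining $entity_b .
  ?ref dcterms:title ?title ;
       dcterms:date ?date ;
       dcterms:isPartOf ?journalNode .
  ?journalNode prism:publicationName ?journal .
  OPTIONAL { ?ref vocab:hasPMCId ?pmcid }
$review_clause$pmc_clause  BIND(xsd:integer(STRAFTER(STR(?ref), "PMID")) AS ?refnum)
}
ORDER BY DESC(?date) DESC(?refnum)
LIMIT $limit
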