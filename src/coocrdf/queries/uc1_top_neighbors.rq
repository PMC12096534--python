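# Top co-occurrence neighbors of one kind for an anchor entity,
# score-descending (e.g. the top-25 diseases co-mentioned with a chemical).
$prefixes

SELECT ?neighbor ?score ?label
WHERE {
  ?assoc rdf:type $assoc_class ;
         rdf:subject $anchor ;
         rdf:object ?neighbor ;
         sio:SIO_000300 ?score .
  OPTIONAL { ?neighbor skos:prefLabel ?label }
}
ORDER BY DESC(?score) ASC(?neighbor)
LIMIT $limit
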