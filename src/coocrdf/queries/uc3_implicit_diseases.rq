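# Diseases implicitly related to a chemical via its top co-mentioned gene:
# the inner query picks the chemical's highest-scoring gene neighbor, the
# outer one returns that gene's top diseases, flagging which are also
# directly co-mentioned with the chemical.
$prefixes

SELECT ?disease ?label ?score ?direct
WHERE {
  {
    SELECT ?gene
    WHERE {
      ?cg rdf:type sio:SIO_001257 ;
          rdf:subject $chemical ;
          rdf:object ?gene ;
          sio:SIO_000300 ?gscore .
    }
    ORDER BY DESC(?gscore) ASC(?gene)
    LIMIT 1
  }
  ?gd rdf:type sio:SIO_000983 ;
      rdf:subject ?gene ;
      rdf:object ?disease ;
      sio:SIO_000300 ?score .
  OPTIONAL { ?disease skos:prefLabel ?label }
  OPTIONAL {
    ?cd rdf:type sio:SIO_000993 ;
        rdf:subject $chemical ;
        rdf:object ?disease .
    BIND(true AS ?found)
  }
  BIND(COALESCE(?found, false) AS ?direct)
}
ORDER BY DESC(?score) ASC(?disease)
LIMIT $limit
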