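# Genes commonly mentioned with two diseases: the inner query takes the
# first disease's top genes by co-occurrence score; the outer one keeps
# those also co-mentioned with the second disease and resolves preferred
# gene names through species-specific gene records (optionally restricted
# to human, NCBI taxon 9606).
$prefixes

SELECT ?gene ?name ?s1 ?s2 ((?s1 + ?s2) AS ?total)
WHERE {
  {
    SELECT ?gene ?s1
    WHERE {
      ?c1 rdf:type sio:SIO_000983 ;
          rdf:subject $disease1 ;
          rdf:object ?gene ;
          sio:SIO_000300 ?s1 .
    }
    ORDER BY DESC(?s1) ASC(?gene)
    LIMIT $inner_limit
  }
  ?c2 rdf:type sio:SIO_000983 ;
      rdf:subject $disease2 ;
      rdf:object ?gene ;
      sio:SIO_000300 ?s2 .
$name_clause}
ORDER BY DESC(?total) ASC(?gene)
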