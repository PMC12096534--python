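# For each compound co-mentioned with every listed gene (inner query),
# count the references that mention the compound AND all the genes in a
# single record; compounds with no such reference drop out of the join.
$prefixes

SELECT ?compound (COUNT(DISTINCT ?ref) AS ?nrefs)
WHERE {
  {
    SELECT DISTINCT ?compound
    WHERE {
$gene_blocks$role_clause    }
  }
  ?ref vocab:discussesAsDerivedByTextMining ?compound .
$ref_gene_lines}
GROUP BY ?compound
ORDER BY DESC(?nrefs) ASC(?compound)
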