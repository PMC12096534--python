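# Compounds co-mentioned with every listed gene (genes are the subjects of
# the chemical-gene associations), optionally restricted to a compound role
# such as FDA-approved drugs, ordered by the sum of the gene->compound
# co-occurrence scores.
$prefixes

SELECT ?compound ?label $score_vars (($score_sum) AS ?total)
WHERE {
$gene_blocks$role_clause  OPTIONAL { ?compound skos:prefLabel ?label }
}
ORDER BY DESC(?total) ASC(?compound)
$limit_clause
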