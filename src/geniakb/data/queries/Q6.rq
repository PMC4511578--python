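SELECT DISTINCT ?s1 ?s2 WHERE { ?t1 a genia:Protein; tao:denoted_by ?s1 . ?t2 a genia:Protein; tao:denoted_by ?s2 . ?t1 genia:themeOf+ ?e1. ?t2 genia:causeOf ?e1.}
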