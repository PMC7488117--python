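Sample	Genotype concordance	Non-reference genotype concordance	Non-reference genotype sensitivity	Sensitivity	Precision	Specificity	Accuracy
001	0.99783	0.99616	0.99687	0.99783	0.99783	0.99925	0.99928
002	0.99156	0.97973	0.98773	0.99156	0.99156	0.99696	0.99718
003	0.99253	0.985	0.98402	0.99253	0.99253	0.99742	0.9975
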