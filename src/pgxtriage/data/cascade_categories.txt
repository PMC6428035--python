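# Cascade count-matrix category manifest: key<TAB>label, in fixed row order.
all	All variants
rare	Rare variants
rare_intronic	Intronic rare
rare_upstream	Upstream rare
rare_downstream	Downstream rare
rare_utr3	Utr3 rare
rare_utr5	Utr5 rare
rare_missense	Missense rare
rare_frameshift	Frameshift rare
rare_synonymous	Synonymous rare
rare_splice_acceptor	Splice acceptor rare
rare_splice_donor	Splice donor rare
rare_stop_gain	Stop gain rare
rare_splice_region	Splice region rare
rare_cadd_gt20	Rare CADD > 20
rare_consensus_missense	Missense rare 4xD + CADD > 20
rare_truncating	HIGH impact rare (truncating variants)
clinvar6_all	ClinVar at least one 6 (all)
clinvar6_rare	ClinVar at least one 6 (rare)
level_1a1b_all	PharmGKB Level 1A/1B (all)
level_1a1b_rare	PharmGKB Level 1A/1B (rare)
level_2a2b_all	PharmGKB Level 2A/2B (all)
level_2a2b_rare	PharmGKB Level 2A/2B (rare)
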