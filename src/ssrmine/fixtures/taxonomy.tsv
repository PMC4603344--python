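genus	group
Oryza	Monocotyledoneae
Arabidopsis	Eudicotyledoneae
Trifolium	Eudicotyledoneae
Centaurea	Eudicotyledoneae
Taiwania	Acrogymnospermae
Urochloa	Monocotyledoneae
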