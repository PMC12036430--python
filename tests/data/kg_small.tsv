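node_a	kind_a	node_b	kind_b	source
DrugA	drug	GeneA	gene	dbX
DrugA	drug	GeneB	gene	dbX
DrugA	drug	GeneC	gene	dbY
DrugB	drug	GeneB	gene	dbX
DrugB	drug	GeneD	gene	dbZ
DrugC	drug	GeneC	gene	dbX
DrugC	drug	GeneE	gene	dbY
DrugD	drug	GeneE	gene	dbX
DrugD	drug	GeneF	gene	dbX
DrugE	drug	GeneF	gene	dbZ
DrugE	drug	GeneG	gene	dbX
DrugF	drug	GeneG	gene	dbY
DrugF	drug	GeneH	gene	dbX
DrugF	drug	GeneA	gene	dbX
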