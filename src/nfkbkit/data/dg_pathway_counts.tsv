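pathway_id	description	pathway_size	hits
hsa04060	Cytokine-cytokine receptor interaction	271	70
hsa04062	Chemokine signaling pathway	186	30
hsa04630	Jak-STAT signaling pathway	154	26
hsa04620	Toll-like receptor signaling pathway	101	23
hsa05222	Small cell lung cancer	90	19
hsa04621	NOD-like receptor signaling pathway	62	17
hsa05215	Prostate cancer	88	17
hsa04210	Apoptosis	86	16
hsa04940	Type I diabetes mellitus	90	16
hsa04672	Intestinal immune network for IgA production	84	15
hsa05330	Allograft rejection	84	15
hsa04640	Hematopoietic cell lineage	87	15
hsa05332	Graft-versus-host disease	87	13
hsa05219	Bladder cancer	42	12
hsa04115	p53 signaling pathway	67	11
hsa05218	Melanoma	70	11
hsa05212	Pancreatic cancer	71	11
hsa04623	Cytosolic DNA-sensing pathway	55	10
hsa05340	Primary immunodeficiency	41	9
hsa05014	Amyotrophic lateral sclerosis	57	9
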