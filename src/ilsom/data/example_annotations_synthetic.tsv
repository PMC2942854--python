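probe_code	at_id	sgn_u	description
LE12J18	At3g09820	SGN-U312345	adenosine kinase-like protein (synthetic example entry)
LE13G19	At5g17330	SGN-U318210	glutamate decarboxylase-like protein (synthetic example entry)
LE22O03	At1g65960	SGN-U320077	amino acid transporter-like protein (synthetic example entry)
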