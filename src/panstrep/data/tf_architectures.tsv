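rule_id	family	required	forbidden	priority
R001	SARP	PF03704,PF00486		10
R002	TetR	PF00440		20
R003	MarR	PF01047		30
R004	LacI	PF00356,PF00532		40
R005	LuxR	PF00196		50
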