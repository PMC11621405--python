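ligand	receptor	source
LigA	RecA	toy
LigB	RecB	toy
LigC	RecC	toy
LigD	RecD	toy
LigE	RecE	toy
LigF	RecF	toy
LigG	RecG	toy
LigH	RecH	toy
LigI	RecI	toy
LigJ	RecJ	toy
g005	g015	toy
g006	g016	toy
g007	g017	toy
g008	g018	toy
g009	g019	toy
g015	g025	toy
g016	g026	toy
g017	g027	toy
g025	g035	toy
g026	g036	toy
g035	g045	toy
g036	g046	toy
g045	g055	toy
g046	g056	toy
g055	g005	toy
g056	g006	toy
g027	g037	toy
g037	g047	toy
g047	g057	toy
g057	g007	toy
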