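calmodulin binding	synthetic padding to curated term size	SPHK1	PNCK	ITPKA	MYO3A	PAD001	PAD002	PAD003	PAD004	PAD005	PAD006	PAD007	PAD008	PAD009	PAD010	PAD011	PAD012	PAD013	PAD014	PAD015	PAD016	PAD017	PAD018	PAD019	PAD020	PAD021	PAD022	PAD023	PAD024	PAD025	PAD026	PAD027	PAD028	PAD029	PAD030	PAD031	PAD032	PAD033	PAD034	PAD035	PAD036	PAD037	PAD038	PAD039	PAD040	PAD041	PAD042	PAD043	PAD044	PAD045	PAD046	PAD047	PAD048	PAD049	PAD050	PAD051	PAD052	PAD053	PAD054	PAD055	PAD056	PAD057	PAD058	PAD059	PAD060	PAD061	PAD062	PAD063	PAD064	PAD065	PAD066	PAD067	PAD068	PAD069	PAD070	PAD071	PAD072	PAD073	PAD074	PAD075	PAD076	PAD077	PAD078	PAD079	PAD080	PAD081	PAD082	PAD083	PAD084	PAD085	PAD086	PAD087	PAD088	PAD089	PAD090	PAD091	PAD092	PAD093	PAD094	PAD095	PAD096	PAD097	PAD098	PAD099	PAD100	PAD101	PAD102	PAD103	PAD104	PAD105	PAD106	PAD107	PAD108	PAD109	PAD110	PAD111	PAD112	PAD113	PAD114	PAD115	PAD116	PAD117	PAD118	PAD119	PAD120	PAD121	PAD122	PAD123	PAD124	PAD125	PAD126	PAD127	PAD128	PAD129	PAD130	PAD131	PAD132	PAD133	PAD134	PAD135	PAD136
calmodulin-dependent protein kinase activity	synthetic padding to curated term size	PNCK	ITPKA	PAD137	PAD138	PAD139	PAD140	PAD141	PAD142	PAD143	PAD144	PAD145	PAD146	PAD147	PAD148
inositol trisphosphate 3-kinase activity	synthetic padding to curated term size	IPMK	ITPKA	PAD149	PAD150	PAD151	PAD152	PAD153
uridine kinase activity	synthetic padding to curated term size	UCK1	PAD154	PAD155	PAD156
nucleoside triphosphate adenylate kinase activity	synthetic padding to curated term size	AK3
phosphomevalonate kinase activity	synthetic padding to curated term size	PMVK
pantetheine-phosphate adenylyltransferase activity	synthetic padding to curated term size	COASY
D-erythro-sphingosine kinase activity	synthetic padding to curated term size	SPHK1
plus-end directed microfilament motor activity	synthetic padding to curated term size	MYO3A
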