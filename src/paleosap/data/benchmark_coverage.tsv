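search_label	accession	position	n_total_psms
Pan	PANI001	50	3
Pan	PANI002	50	3
Pan	PANI003	50	3
Pan	PANI004	50	3
Pan	PANI005	50	3
Pan	PANI006	50	3
Pan	PANI007	50	3
Pan	PANI008	50	3
Pan	PANI009	50	3
Pan	PANI010	50	3
Pan	PANI011	50	3
Pan	PANI012	50	3
Pan	PANI013	50	3
Pan	PANI014	50	3
Pan	PANI015	50	3
Pan	PANI016	50	3
Pan	PANI017	50	3
Pan	PANI018	50	3
Pan	PANI019	50	3
Pan	PANI020	50	3
Pan	PANI021	50	3
Pan	PANI022	50	3
Pan	PANI023	50	3
Pan	PANI024	50	3
Pan	PANI025	50	3
Pan	PANI026	50	3
Pan	PANI027	50	3
Pan	PANI028	50	3
Pan	PANI029	50	3
Pan	PANI030	50	3
Pan	PANI031	50	3
Pan	PANI032	50	3
Pan	PANS001	60	2
Pan	PANS002	60	2
Pan	PANS003	60	2
Pan	PANS004	60	2
Pan	PANS005	60	2
Pan	PANS006	60	2
Pan	PANS007	60	2
Pan	PANS008	60	2
Pan	PANS009	60	2
Pan	PANS010	60	2
Pan	PANS011	60	2
Pan	PANS012	60	2
Pan	PANS013	60	2
Pan	PAND001	70	2
Pan	PAND002	70	2
Pan	PAND003	70	2
Pan	PAND004	70	2
Pan	PAND005	70	2
Pan	PAND006	70	2
Pan	PAND007	70	2
Pan	PAND008	70	2
Pan	PAND009	70	2
Pan	PAND010	70	2
Pan	PAND011	70	2
Pan	PAND012	70	2
Pan	PAND013	70	2
Pan	PAND014	70	2
Pan	PAND015	70	2
Pan	PAND016	70	2
Pan	PAND017	70	2
Pan	PAND018	70	2
Pan	PAND019	70	2
Pan	PAND020	70	2
Pan	PAND021	70	2
Pan	PAND022	70	2
Pan	PAND023	70	2
Pan	PAND024	70	2
Pan	PAND025	70	2
Pan	PAND026	70	2
Pan	PAND027	70	2
Pan	PAND028	70	2
Pan	PAND029	70	2
Pan	PAND030	70	2
Pan	PAND031	70	2
Pan	PAND032	70	2
Pan	PAND033	70	2
Pan	PAND034	70	2
Pan	PAND035	70	2
Pan	PAND036	70	2
Pan	PAND037	70	2
Pan	PAND038	70	2
Pan	PAND039	70	2
Pan	PAND040	70	2
Pan	PAND041	70	2
Pan	PAND042	70	2
Pan	PAND043	70	2
Pan	PAND044	70	2
Pan	PAND045	70	2
Pan	PAND046	70	2
Pan	PAND047	70	2
Pan	PAND048	70	2
Pan	PAND049	70	2
Pan	PAND050	70	2
Pan	PAND051	70	2
Pan	PAND052	70	2
Pan	PAND053	70	2
Pan	PAND054	70	2
Pan	PAND055	70	2
Pan	PANT001	80	4
Pan	PANT002	80	4
Pan	PANT003	80	4
Pan	PANT004	80	4
Pan	PANT005	80	4
Pongo	PGI001	50	3
Pongo	PGI002	50	3
Pongo	PGI003	50	3
Pongo	PGI004	50	3
Pongo	PGI005	50	3
Pongo	PGI006	50	3
Pongo	PGI007	50	3
Pongo	PGI008	50	3
Pongo	PGI009	50	3
Pongo	PGI010	50	3
Pongo	PGI011	50	3
Pongo	PGI012	50	3
Pongo	PGI013	50	3
Pongo	PGI014	50	3
Pongo	PGI015	50	3
Pongo	PGI016	50	3
Pongo	PGI017	50	3
Pongo	PGI018	50	3
Pongo	PGI019	50	3
Pongo	PGI020	50	3
Pongo	PGI021	50	3
Pongo	PGI022	50	3
Pongo	PGI023	50	3
Pongo	PGI024	50	3
Pongo	PGI025	50	3
Pongo	PGI026	50	3
Pongo	PGI027	50	3
Pongo	PGI028	50	3
Pongo	PGI029	50	3
Pongo	PGI030	50	3
Pongo	PGI031	50	3
Pongo	PGI032	50	3
Pongo	PGI033	50	3
Pongo	PGI034	50	3
Pongo	PGI035	50	3
Pongo	PGI036	50	3
Pongo	PGI037	50	3
Pongo	PGI038	50	3
Pongo	PGI039	50	3
Pongo	PGI040	50	3
Pongo	PGI041	50	3
Pongo	PGI042	50	3
Pongo	PGI043	50	3
Pongo	PGI044	50	3
Pongo	PGI045	50	3
Pongo	PGI046	50	3
Pongo	PGI047	50	3
Pongo	PGI048	50	3
Pongo	PGI049	50	3
Pongo	PGI050	50	3
Pongo	PGI051	50	3
Pongo	PGI052	50	3
Pongo	PGI053	50	3
Pongo	PGI054	50	3
Pongo	PGI055	50	3
Pongo	PGI056	50	3
Pongo	PGI057	50	3
Pongo	PGI058	50	3
Pongo	PGI059	50	3
Pongo	PGI060	50	3
Pongo	PGI061	50	3
Pongo	PGI062	50	3
Pongo	PGI063	50	3
Pongo	PGI064	50	3
Pongo	PGI065	50	3
Pongo	PGI066	50	3
Pongo	PGS001	60	2
Pongo	PGS002	60	2
Pongo	PGS003	60	2
Pongo	PGS004	60	2
Pongo	PGS005	60	2
Pongo	PGS006	60	2
Pongo	PGS007	60	2
Pongo	PGS008	60	2
Pongo	PGS009	60	2
Pongo	PGS010	60	2
Pongo	PGS011	60	2
Pongo	PGS012	60	2
Pongo	PGS013	60	2
Pongo	PGS014	60	2
Pongo	PGS015	60	2
Pongo	PGS016	60	2
Pongo	PGS017	60	2
Pongo	PGS018	60	2
Pongo	PGS019	60	2
Pongo	PGS020	60	2
Pongo	PGS021	60	2
Pongo	PGS022	60	2
Pongo	PGS023	60	2
Pongo	PGS024	60	2
Pongo	PGD001	70	2
Pongo	PGD002	70	2
Pongo	PGD003	70	2
Pongo	PGD004	70	2
Pongo	PGD005	70	2
Pongo	PGD006	70	2
Pongo	PGD007	70	2
Pongo	PGD008	70	2
Pongo	PGD009	70	2
Pongo	PGD010	70	2
Pongo	PGD011	70	2
Pongo	PGD012	70	2
Pongo	PGD013	70	2
Pongo	PGD014	70	2
Pongo	PGD015	70	2
Pongo	PGD016	70	2
Pongo	PGD017	70	2
Pongo	PGD018	70	2
Pongo	PGD019	70	2
Pongo	PGD020	70	2
Pongo	PGD021	70	2
Pongo	PGD022	70	2
Pongo	PGD023	70	2
Pongo	PGD024	70	2
Pongo	PGD025	70	2
Pongo	PGD026	70	2
Pongo	PGD027	70	2
Pongo	PGD028	70	2
Pongo	PGD029	70	2
Pongo	PGD030	70	2
Pongo	PGD031	70	2
Pongo	PGD032	70	2
Pongo	PGD033	70	2
Pongo	PGD034	70	2
Pongo	PGD035	70	2
Pongo	PGD036	70	2
Pongo	PGD037	70	2
Pongo	PGD038	70	2
Pongo	PGD039	70	2
Pongo	PGD040	70	2
Pongo	PGD041	70	2
Pongo	PGD042	70	2
Pongo	PGD043	70	2
Pongo	PGD044	70	2
Pongo	PGD045	70	2
Pongo	PGD046	70	2
Pongo	PGD047	70	2
Pongo	PGD048	70	2
Pongo	PGD049	70	2
Pongo	PGD050	70	2
Pongo	PGD051	70	2
Pongo	PGD052	70	2
Pongo	PGD053	70	2
Pongo	PGD054	70	2
Pongo	PGD055	70	2
Pongo	PGD056	70	2
Pongo	PGD057	70	2
Pongo	PGD058	70	2
Pongo	PGD059	70	2
Pongo	PGD060	70	2
Pongo	PGD061	70	2
Pongo	PGD062	70	2
Pongo	PGD063	70	2
Pongo	PGD064	70	2
Pongo	PGD065	70	2
Pongo	PGD066	70	2
Pongo	PGD067	70	2
Pongo	PGD068	70	2
Pongo	PGD069	70	2
Pongo	PGD070	70	2
Pongo	PGD071	70	2
Pongo	PGD072	70	2
Pongo	PGD073	70	2
Pongo	PGD074	70	2
Pongo	PGD075	70	2
Pongo	PGD076	70	2
Pongo	PGD077	70	2
Pongo	PGD078	70	2
Pongo	PGD079	70	2
Pongo	PGD080	70	2
Pongo	PGD081	70	2
Pongo	PGD082	70	2
Pongo	PGD083	70	2
Pongo	PGD084	70	2
Pongo	PGD085	70	2
Pongo	PGD086	70	2
Pongo	PGD087	70	2
Pongo	PGD088	70	2
Pongo	PGD089	70	2
Pongo	PGD090	70	2
Pongo	PGD091	70	2
Pongo	PGD092	70	2
Pongo	PGD093	70	2
Pongo	PGD094	70	2
Pongo	PGD095	70	2
Pongo	PGD096	70	2
Pongo	PGD097	70	2
Pongo	PGD098	70	2
Pongo	PGD099	70	2
Pongo	PGD100	70	2
Pongo	PGD101	70	2
Pongo	PGD102	70	2
Pongo	PGD103	70	2
Pongo	PGD104	70	2
Pongo	PGD105	70	2
Pongo	PGD106	70	2
Pongo	PGD107	70	2
Pongo	PGD108	70	2
Pongo	PGD109	70	2
Pongo	PGD110	70	2
Pongo	PGD111	70	2
Pongo	PGD112	70	2
Pongo	PGD113	70	2
Pongo	PGD114	70	2
Pongo	PGD115	70	2
Pongo	PGD116	70	2
Pongo	PGD117	70	2
Pongo	PGD118	70	2
Pongo	PGD119	70	2
Pongo	PGD120	70	2
Pongo	PGD121	70	2
Pongo	PGD122	70	2
Pongo	PGD123	70	2
Pongo	PGD124	70	2
Pongo	PGD125	70	2
Pongo	PGD126	70	2
Pongo	PGD127	70	2
Pongo	PGD128	70	2
Pongo	PGD129	70	2
Pongo	PGD130	70	2
Pongo	PGD131	70	2
Pongo	PGD132	70	2
Pongo	PGD133	70	2
Pongo	PGD134	70	2
Pongo	PGD135	70	2
Pongo	PGD136	70	2
Pongo	PGD137	70	2
Pongo	PGD138	70	2
Pongo	PGD139	70	2
Pongo	PGD140	70	2
Pongo	PGD141	70	2
Pongo	PGD142	70	2
Pongo	PGD143	70	2
Pongo	PGD144	70	2
Pongo	PGD145	70	2
Pongo	PGD146	70	2
Pongo	PGD147	70	2
Pongo	PGD148	70	2
Pongo	PGD149	70	2
Pongo	PGD150	70	2
Pongo	PGD151	70	2
Pongo	PGD152	70	2
Pongo	PGD153	70	2
Pongo	PGD154	70	2
Pongo	PGD155	70	2
Pongo	PGD156	70	2
Pongo	PGD157	70	2
Pongo	PGD158	70	2
Pongo	PGD159	70	2
Pongo	PGD160	70	2
Pongo	PGQ001	80	5
Pongo	PGQ002	80	5
Pongo	PGM001	40	2
Pongo	PGM001	48	2
Pongo	PGM002	40	2
Pongo	PGM002	48	2
Pongo	PGM003	40	2
Pongo	PGM003	48	2
Pongo	PGM004	40	2
Pongo	PGM004	48	2
Pongo	PGM005	40	2
Pongo	PGM005	48	2
Pongo	PGM006	40	2
Pongo	PGM006	48	2
Pongo	PGM007	40	3
Pongo	PGM007	48	3
Pongo	PGX001	40	2
Pongo	PGX001	48	5
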