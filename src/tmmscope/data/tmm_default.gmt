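Tel_TERT	Tel_TERT	G0001	G0002	G0003	G0004	G0005	G0006	G0007	G0008	G0009	G0010	G0011	G0012	G0013	G0014	G0015	G0016	G0017	G0018	G0019
Tel_TERC_DKC1	Tel_TERC_DKC1	G0020	G0021	G0022	G0023	G0024	G0025	G0026	G0027	G0028	G0029	G0030	G0031	G0032	G0033	G0034	G0035	G0036	G0037	G0038
ALT_HR	ALT_HR	G0039	G0040	G0041	G0042	G0043	G0044	G0045	G0046	G0047	G0048	G0049	G0050	G0051	G0052	G0053
ALT_CHR	ALT_CHR	G0054	G0055	G0056	G0057	G0058	G0059	G0060	G0061	G0062	G0063	G0064	G0065	G0066	G0067	G0068
ALT_PML	ALT_PML	G0069	G0070	G0071	G0072	G0073	G0074	G0075	G0076	G0077	G0078	G0079	G0080	G0081	G0082	G0083
ALT_ins	ALT_ins	G0084	G0085	G0086	G0087	G0088	G0089	G0090	G0091	G0092	G0093	G0094	G0095	G0096	G0097
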