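site_id	zone	location	latitude	longitude	precipitation_mm
BZ	humid	Bizerte	37.1227	9.54539	800-1200
BA1	semi_arid	Bou Argoub	36.5056	10.5222	400-600
BA2	semi_arid	Bou Argoub	36.5073	10.4164	400-600
BA3	semi_arid	Bou Argoub	36.5056	10.4322	400-600
KA1	semi_arid	Kairouan	35.3806	9.3004	400-600
KA2	semi_arid	Kairouan	35.3942	9.2859	400-600
KA3	semi_arid	Kairouan	35.4008	10.005	400-600
KS1	upper_arid	Kasserin	35.2112	8.4806	200-400
KS2	upper_arid	Kasserin	35.2111	8.4750	200-400
KS3	upper_arid	Kasserin	35.2223	8.4631	200-400
KS4	upper_arid	Kasserin	35.2234	8.4632	200-400
KS5	upper_arid	Kasserin	35.2244	8.4632	200-400
KS6	upper_arid	Kasserin	35.2921	8.6621	200-400
SB1	upper_arid	Sidi Bouzid	35.3123	9.2129	200-400
SB2	upper_arid	Sidi Bouzid	35.1719	9.2701	200-400
SB3	upper_arid	Sidi Bouzid	35.3123	9.2701	200-400
GF1	lower_arid	Gafsa	34.1504	9.1716	100-200
GF2	lower_arid	Gafsa	34.1502	9.1713	100-200
GF3	lower_arid	Gafsa	35.5547	10.1754	100-200
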