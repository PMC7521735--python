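# Published HepG2 SRXN1-GFP confirmation screen: per-chemical designation of
# the biomarker prediction against the reporter-assay outcome.
# designation: TP/FP/TN/FN enter the accuracy arithmetic; PC = positive
# control, NU = not used, 1/2 = concentration ranges incomparable (excluded).
chemical	biomarker_max_score	reporter_result	designation
2-Nitrofluorene	6	Active	TP
Acetaminophen	6.522879	Inactive	2
Allyl alcohol	7.022276	Active	TP
Atorvastatin	11.40894	Inactive	FP
Benzoin	9.091515	Inactive	2
Carbamazepine	7.065502	Active	TP
Coumaphos	1.793174	Active	FN
Coumarin	6.69897	Inactive	2
Danazol	3.39794	Active	1
Diethylstilbestrol	8.585027	Active	TP
Disulfiram	5.823909	Inactive	FP
Fenofibrate	0.556737	Inactive	TN
Hydroquinone	1.549751	Active	1
Indomethacin	3.69897	Active	FN
LY294002	-5.638	Active	NU
Mefenamic acid	4	Active	1
Pentachlorophenol	1.752027	Active	1
Progesterone	0	Inactive	TN
Propiconazole	1.847712	Inactive	TN
Quercetin	26.48149	Active	PC
Resorcinol	10.40894	Active	TP
Simazine	-0.96981	Inactive	TN
Simvastatin	0.407601	Inactive	TN
Sulfisoxazole	-2.92082	Inactive	TN
Sulindac	11.85387	Active	PC
Tamoxifen	0	Inactive	TN
Tetracycline	10.88606	Active	TP
Tolbutamide	9.744727	Inactive	2
Triclosan	-0.61834	Inactive	TN
Valproic acid	1.171985	Inactive	TN
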