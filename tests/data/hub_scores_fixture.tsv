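hub_cui	hub_name	candidate_cui	candidate_name	candidate_semtype	normalized_score
C9100007	Granuloma	C9200001	Vancomycin	PHSU	0.927
C9100009	Liver Injury	C9200001	Vancomycin	PHSU	0.499
C9100010	Renal	C9200001	Vancomycin	PHSU	0.341
C9100008	Hypomyelination	C9200001	Vancomycin	PHSU	0.333
C9100011	SLC33A1	C9200001	Vancomycin	PHSU	0.272
C9100006	GYPE	C9200001	Vancomycin	PHSU	0.265
C9100003	DRD2	C9200001	Vancomycin	PHSU	0.251
C9100004	EEF1A2	C9200001	Vancomycin	PHSU	0.245
C9100008	Hypomyelination	C9200002	Captopril	PHSU	0.474
C9100002	Dopamine	C9200002	Captopril	PHSU	0.462
C9100010	Renal	C9200002	Captopril	PHSU	0.436
C9100011	SLC33A1	C9200002	Captopril	PHSU	0.335
C9100005	GRM1	C9200002	Captopril	PHSU	0.271
C9100006	GYPE	C9200002	Captopril	PHSU	0.249
C9100004	EEF1A2	C9200002	Captopril	PHSU	0.247
C9100003	DRD2	C9200002	Captopril	PHSU	0.237
C9100011	SLC33A1	C9200003	Neramexane	PHSU	0.765
C9100001	Antihistamine	C9200003	Neramexane	PHSU	0.706
C9100004	EEF1A2	C9200003	Neramexane	PHSU	0.629
C9100003	DRD2	C9200003	Neramexane	PHSU	0.505
C9100005	GRM1	C9200003	Neramexane	PHSU	0.492
C9100006	GYPE	C9200003	Neramexane	PHSU	0.408
C9100004	EEF1A2	C9200004	Levocetirizine	PHSU	0.455
C9100002	Dopamine	C9200004	Levocetirizine	PHSU	0.391
C9100003	DRD2	C9200004	Levocetirizine	PHSU	0.375
C9100011	SLC33A1	C9200004	Levocetirizine	PHSU	0.316
C9100011	SLC33A1	C9200005	Ebastine	PHSU	0.585
C9100001	Antihistamine	C9200005	Ebastine	PHSU	0.446
C9100003	DRD2	C9200005	Ebastine	PHSU	0.399
C9100004	EEF1A2	C9200005	Ebastine	PHSU	0.398
C9100005	GRM1	C9200005	Ebastine	PHSU	0.369
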