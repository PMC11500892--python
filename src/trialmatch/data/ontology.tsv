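code	preferred_name	synonyms	parents
C3262	Neoplasm	neoplasm|tumor|neoplasms
C9305	Malignant Neoplasm	cancer|malignancy|malignant tumor	C3262
C9292	Solid Neoplasm	solid tumor|solid tumors	C9305
C3520	Metastatic Neoplasm	metastatic tumor|metastatic cancer	C9305
C4897	Benign Neoplasm	benign tumor	C3262
C3849	Lipoma		C4897
C2916	Carcinoma		C9305
C9118	Sarcoma		C9305
C3224	Melanoma	malignant melanoma	C9305
C3208	Lymphoma		C9305
C3161	Leukemia		C9305
C3059	Glioma		C9305
C2852	Adenocarcinoma		C2916
C2929	Squamous Cell Carcinoma	squamous carcinoma	C2916
C4878	Lung Carcinoma	lung cancer|carcinoma of the lung	C2916
C2926	Non-Small Cell Lung Carcinoma	NSCLC	C4878
C4917	Small Cell Lung Carcinoma	SCLC	C4878
C3512	Lung Adenocarcinoma	adenocarcinoma of the lung	C2852|C2926
C3510	Lung Squamous Cell Carcinoma	squamous cell carcinoma of the lung	C2929|C2926
C5105	Colorectal Carcinoma	colorectal cancer	C2916
C4910	Colon Carcinoma	colon cancer	C5105
C4349	Colon Adenocarcinoma	adenocarcinoma of the colon	C2852|C4910
C7418	Rectal Adenocarcinoma	adenocarcinoma of the rectum	C2852|C5105
C3305	Pancreatic Carcinoma	pancreatic cancer	C2916
C8294	Pancreatic Adenocarcinoma	pancreas adenocarcinoma|adenocarcinoma of the pancreas	C2852|C3305
C4911	Gastric Carcinoma	gastric cancer|stomach cancer	C2916
C4004	Gastric Adenocarcinoma	stomach adenocarcinoma|adenocarcinoma of the stomach	C2852|C4911
C4872	Breast Carcinoma	breast cancer	C2916
C9131	Triple-Negative Breast Carcinoma	TNBC	C4872
C4863	Prostate Carcinoma	prostate cancer	C2916
C2919	Prostate Adenocarcinoma	adenocarcinoma of the prostate	C2852|C4863
C4908	Ovarian Carcinoma	ovarian cancer	C2916
C7700	Ovarian Serous Adenocarcinoma	serous ovarian adenocarcinoma	C2852|C4908
C3099	Hepatocellular Carcinoma	HCC|hepatocellular cancer	C2916
C9385	Renal Cell Carcinoma	RCC|kidney cancer	C2916
C4912	Bladder Carcinoma	bladder cancer	C2916
C4030	Urothelial Carcinoma	transitional cell carcinoma	C4912
C6010	Head and Neck Squamous Cell Carcinoma	HNSCC	C2929
C4025	Esophageal Carcinoma	esophageal cancer	C2916
C4026	Esophageal Squamous Cell Carcinoma		C2929|C4025
C4024	Cervical Carcinoma	cervical cancer	C2916
C7558	Endometrial Carcinoma	endometrial cancer	C2916
C4015	Thyroid Carcinoma	thyroid cancer	C2916
C2853	Mucinous Adenocarcinoma		C2852
C5103	Appendix Mucinous Adenocarcinoma	mucinous adenocarcinoma of the appendix	C2853
C3802	Cutaneous Melanoma	melanoma of the skin	C3224
C7712	Uveal Melanoma		C3224
C9145	Osteosarcoma	osteogenic sarcoma	C9118
C3158	Leiomyosarcoma		C9118
C3194	Liposarcoma		C9118
C4244	Atypical Lipomatous Tumor	ALT|well-differentiated liposarcoma	C3194
C4817	Ewing Sarcoma	ewings sarcoma	C9118
C9306	Soft Tissue Sarcoma	STS	C9118
C9087	Hodgkin Lymphoma	hodgkins lymphoma	C3208
C3211	Non-Hodgkin Lymphoma	NHL	C3208
C8851	Diffuse Large B-Cell Lymphoma	DLBCL	C3211
C3171	Acute Myeloid Leukemia	AML	C3161
C3163	Chronic Lymphocytic Leukemia	CLL	C3161
C3058	Glioblastoma	GBM|glioblastoma multiforme	C3059
C4290	Metastatic Malignant Neoplasm in the Liver	liver metastasis|liver metastases	C3520
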