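sequence	species	protein	functions	reference
ENLHLPLP	both	beta-casein	ACE-inhibitory	MBPDB
ENLHLPLPLL	both	beta-casein	ACE-inhibitory	MBPDB
LHLPLPL	both	beta-casein	ACE-inhibitory	MBPDB
AEIYGTKESPQTHYY	bovine	lactoferrin	Stimulates Proliferation	MBPDB
AYFYPEL	bovine	alpha-s1-casein	ACE-inhibitory;Antioxidant;Increase MUC5AC Expression;Opioid	MBPDB
DAYPSGAW	bovine	alpha-s1-casein	ACE-inhibitory	MBPDB
FPEVFGK	bovine	alpha-s1-casein	ACE-inhibitory	MBPDB
FVAPFPEVFG	bovine	alpha-s1-casein	ACE-inhibitory	MBPDB
HIQKEDVPSERYLGYLEQLLRLK	bovine	alpha-s1-casein	Antimicrobial	MBPDB
LAYFYPEL	bovine	alpha-s1-casein	Immunomodulatory	MBPDB
LRLKKYKVPQL	bovine	alpha-s1-casein	Antimicrobial	MBPDB
RPKHPIKHQGLPQEVLNENLLRF	bovine	alpha-s1-casein	Antimicrobial	MBPDB
SDIPNPIGSENSEK	bovine	alpha-s1-casein	Antimicrobial	MBPDB
VLNENLLR	bovine	alpha-s1-casein	Antimicrobial	MBPDB
KTVYQHQKAMKPWIQPKTKVIPYVRYL	bovine	alpha-s2-casein	Antimicrobial	MBPDB
LKKISQRYQKFALPQY	bovine	alpha-s2-casein	Antimicrobial	MBPDB
LKTVYQHQKAMKPWIQPKTKVIPYVRYL	bovine	alpha-s2-casein	Antimicrobial	MBPDB
PYVRYL	bovine	alpha-s2-casein	ACE-inhibitory;Antimicrobial;Antioxidant	MBPDB
TKKTKLTEEEKNRL	bovine	alpha-s2-casein	Antimicrobial	MBPDB
TKVIPYVRYL	bovine	alpha-s2-casein	Antimicrobial	MBPDB
VYQHQKAMKPWIQPKTKVIPYVRYL	bovine	alpha-s2-casein	Antimicrobial	MBPDB
YQKFPQY	bovine	alpha-s2-casein	ACE-inhibitory;Antioxidant	MBPDB
EPVLGPVRGPFP	bovine	beta-casein	ACE-inhibitory	MBPDB
LLYQEPVLGPVRGPFPIIV	bovine	beta-casein	ACE-inhibitory	MBPDB
LNVPGEIVE	bovine	beta-casein	ACE-inhibitory	MBPDB
LVYPFPGPIP	bovine	beta-casein	ACE-inhibitory	MBPDB
NIPPLTQTPV	bovine	beta-casein	ACE-inhibitory	MBPDB
PVVVPPFLQPE	bovine	beta-casein	Antimicrobial	MBPDB
QEPVLGPVRGPFPIIV	bovine	beta-casein	ACE-inhibitory	MBPDB
RDMPIQAF	bovine	beta-casein	ACE-inhibitory	MBPDB
RELEELNVPGEIVESLSSSEESITR	bovine	beta-casein	Caseinophosphopeptide	MBPDB
VLPVPQKAVPYPQR	bovine	beta-casein	Antimicrobial	MBPDB
VYPFPGPIP	bovine	beta-casein	PEP-inhibitory	MBPDB
VYPFPGPIPN	bovine	beta-casein	ACE-inhibitory;Antioxidant	MBPDB
YQEPVLGPVR	bovine	beta-casein	ACE-inhibitory	MBPDB
YQEPVLGPVRG	bovine	beta-casein	ACE-inhibitory	MBPDB
YQEPVLGPVRGPFPI	bovine	beta-casein	Antimicrobial	MBPDB
YQEPVLGPVRGPFPIIV	bovine	beta-casein	ACE-inhibitory;Antimicrobial;Antithrombin;Immunomodulatory	MBPDB
AASDISLLDAQSAPLR	bovine	beta-lactoglobulin	Antimicrobial	MBPDB
DAQSAPLRVY	bovine	beta-lactoglobulin	ACE-inhibitory	MBPDB
GLDIQKVAGT	bovine	beta-lactoglobulin	Antimicrobial	MBPDB
IIAEKTKIPAVF	bovine	beta-lactoglobulin	Antimicrobial	MBPDB
IPAVFKIDA	bovine	beta-lactoglobulin	DPP-IV-Inhibitory	MBPDB
IQKVAGTW	bovine	beta-lactoglobulin	ACE-inhibitory;DPP-IV-Inhibitory	MBPDB
LDIQKVAGTW	bovine	beta-lactoglobulin	ACE-inhibitory	MBPDB
LIVTQTMK	bovine	beta-lactoglobulin	Cytotoxic	MBPDB
LKPTPEGDLE	bovine	beta-lactoglobulin	DPP-IV-Inhibitory	MBPDB
SLAMAASDISLL	bovine	beta-lactoglobulin	Antimicrobial	MBPDB
TPEVDDEALEK	bovine	beta-lactoglobulin	Antimicrobial;DPP-IV-Inhibitory	MBPDB
HPHPHLSF	bovine	kappa-casein	ACE-inhibitory	MBPDB
INNQFLPYPY	bovine	kappa-casein	DPP-IV-Inhibitory	MBPDB
MAIPPKKNQDKTEIPTINT	bovine	kappa-casein	Antimicrobial	MBPDB
VQVTSTAV	bovine	kappa-casein	Antimicrobial	MBPDB
LENLHLPLP	human	beta-casein	ACE-inhibitory	MBPDB
QELLLNPTHQIYPVTQPLAPVHNPISV	human	beta-casein	Antimicrobial	MBPDB
SPTIPFFDPQIPK	human	beta-casein	Stimulates Proliferation	MBPDB
WSVPQPK	human	beta-casein	ACE-inhibitory	MBPDB
YANPAVVRP	human	kappa-casein	ACE-inhibitory	MBPDB
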