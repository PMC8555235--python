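name,description,mean,dispersion,family,shape1,shape2,role
pes,Probability of esophageal stenosis,0.0476,0.0005,beta,4,80,probability
phem,Probability of hemorrhage,0.0243,0.0001,beta,6,241,probability
pho_adj,Probability of hospital readmission after adjuvant,0.1731,0.0027,beta,9,43,probability
pho_s,Probability of hospital readmission (TORS or TLM),0.0333,0.0010,beta,1,29,probability
plg,Probability of long-term gastrostomy (1 year) after adjuvant treatment,0.0500,0.0003,beta,9,171,probability
plt,Probability of long-term tracheostomy (1 year),0.0226,0.0001,beta,4,173,probability
psg,Probability of short-term (6 months) gastrostomy (TORS or TLM),0.0144,0.0001,beta,2,137,probability
psg_adj,Probability of short-term (6 months) gastrostomy after adjuvant,0.2991,0.0019,beta,32,75,probability
por,Probability of osteoradionecrosis,0.0265,0.0002,beta,4,147,probability
ppf,Probability of pharyngocutaneous fistula,0.0253,0.0001,beta,10,385,probability
pTLMAlone,Probability of TLM alone,0.4085,0.0007,beta,134,194,probability
pTorsAlone,Probability of TORS alone,0.3740,0.0001,beta,824,1379,probability
pCRT_TLM,Probability of adjuvant CRT (TLM),0.6289,0.0012,beta,122,72,probability
pCRT_tors,Probability of adjuvant CRT (TORS),0.5272,0.0002,beta,727,652,probability
pRT_TLM,Probability of adjuvant RT (TLM),0.3711,0.0012,beta,72,122,probability
pRT_tors,Probability of adjuvant RT (TORS),0.4728,0.0002,beta,652,727,probability
plr,Probability of local recurrence (first 2 years),0.0064,0.0000,beta,11,1715,probability
prr,Probability of regional recurrence (first 2 years),0.0064,0.0000,beta,11,1715,probability
pdr,Probability of distant recurrence (first 2 years),0.0038,0.0000,beta,11,2900,probability
cTORS,Cost of TORS,14739,869.31,gamma,287.4635,0.0195,cost
cTLM,Cost of TLM,12671,516.23,gamma,602.4698,0.0475,cost
cCRT,Cost of adjuvant CRT,33911,2079.08,gamma,266.0350,0.0078,cost
cRT,Cost of adjuvant RT,27962,1714.35,gamma,266.0342,0.0095,cost
cES,Cost of esophageal stenosis,2362,410.65,gamma,33.0832,0.0140,cost
cGAST,Cost of gastrostomy,4332,410.65,gamma,111.2820,0.0257,cost
cHR_adj,Cost of hospital readmission (for adjuvant),10097,619.05,gamma,266.0342,0.0263,cost
cHR_s,Cost of hospital readmission (TORS or TLM),8203,803.41,gamma,104.2498,0.0127,cost
cORN,Cost of osteoradionecrosis,32111,1077.71,gamma,887.7769,0.0276,cost
cPF,Cost of pharyngocutaneous fistula,82892,333.96,gamma,61609.3654,0.7432,cost
cPH,Cost of hemorrhage (from surgical site),4469,415.50,gamma,115.6865,0.0259,cost
cTRACH,Cost of tracheostomy,11688,612.67,gamma,363.9366,0.0311,cost
cREM,Cost of remission 0-2 y,168.5,9.68,gamma,303.2588,1.7998,cost
c2REM,Cost of remission 2-5 y,60,9.68,gamma,38.4518,0.6409,cost
cPC,Cost of palliative care,4137,367.86,gamma,126.4754,0.0306,cost
cRR,Cost of regional recurrence,7047,464.24,gamma,230.4227,0.0327,cost
cLR_chemorad,Cost of local recurrence (chemoradiation),34041,2079.08,gamma,268.0786,0.0079,cost
cLR_s,Cost of local recurrence (surgical resection),40513,2050.27,gamma,390.4511,0.0096,cost
cDM,Cost of distant metastasis,4137,367.86,gamma,126.4754,0.0306,cost
cPanendo,Cost of panendoscopy,388,23.79,gamma,266.0337,0.6857,cost
uSURG,Utility coefficient of TORS or TLM,0.902,0.203,beta,1.0328,0.1122,utility
uRT,Utility coefficient of adjuvant RT,0.850,0.275,beta,0.5831,0.1029,utility
uCRT,Utility coefficient of adjuvant CRT,0.794,0.317,beta,0.4984,0.1293,utility
uHR,Utility coefficient of hospital readmission,0.954,0.140,beta,1.1820,0.0570,utility
uPF,Utility coefficient of pharyngocutaneous fistula,0.932,0.194,beta,0.6374,0.0465,utility
uPH,Utility coefficient of postoperative hemorrhage,0.910,0.203,beta,0.8986,0.0889,utility
ug,Utility coefficient of gastrostomy,0.916,0.209,beta,0.6975,0.0640,utility
ult,Utility coefficient of long-term tracheostomy,0.852,0.271,beta,0.6109,0.1061,utility
ues,Utility coefficient of esophageal stenosis,0.826,0.284,beta,0.6459,0.1361,utility
uORN,Utility coefficient of osteoradionecrosis,0.791,0.302,beta,0.6428,0.1698,utility
urem,Utility coefficient of remission after surgery and adjuvant,0.957,0.151,beta,0.7702,0.0346,utility
uremonlysurg,Utility coefficient of remission after TORS or TLM alone,0.980,0.099,beta,0.9798,0.0200,utility
ureg,Utility coefficient of regional recurrence,0.859,0.283,beta,0.4401,0.0722,utility
ulocxrt,"Utility coefficient of local recurrence, RT",0.771,0.302,beta,0.7216,0.2143,utility
uloc,"Utility coefficient of local recurrence, requiring surgery",0.755,0.316,beta,0.6436,0.2088,utility
udist,Utility coefficient of distant recurrence,0.307,0.350,beta,0.2262,0.5106,utility
upall,Utility coefficient of palliative care,0.213,0.336,beta,0.1033,0.3816,utility
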