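medication,chemotherapy,platinum,targeted,checkpoint
paclitaxel,1,0,0,0
docetaxel,1,0,0,0
pemetrexed,1,0,0,0
gemcitabine,1,0,0,0
vinorelbine,1,0,0,0
etoposide,1,0,0,0
carboplatin,1,1,0,0
cisplatin,1,1,0,0
oxaliplatin,1,1,0,0
erlotinib,0,0,1,0
gefitinib,0,0,1,0
osimertinib,0,0,1,0
afatinib,0,0,1,0
crizotinib,0,0,1,0
alectinib,0,0,1,0
lorlatinib,0,0,1,0
pembrolizumab,0,0,0,1
nivolumab,0,0,0,1
atezolizumab,0,0,0,1
durvalumab,0,0,0,1
ipilimumab,0,0,0,1
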