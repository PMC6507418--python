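name	declared_length	notation
Adapter1	17	5’pCTGTAGGCACCATCAAT-R-NH2
Adapter2	18	5’ACGGAATTCCTCACTrArArA
Adapter3	22	5’pCAGATCGGAAGAGCACACGTCT-R-NH2
Adapter4	21	5’AppAGATCGGAAGAGCACACGTCT-R-NH2
Adapter5	26	5’rGrUrUrCrArGrArGrUrUrCrUrArCrArGrUrCrCrGrArCrGrArUrC
M1	19	5’rCrGrUrArCrGrCrGrGrGrUrUrUrArArArCrGrA
M2	24	5’rCrGrUrArCrGrCrGrGrArArUrArGrUrUrUrArArArCrUrGrU
RTprimer1	43	5’pACGCTCTCCATGCCACAGGTrCTCCGGATTGATGGTGCCTACAG
Primer1F	21	5’CCGG3ATTGATGGTGCCTACAG
Primer1R	22	5’AGACCTGTGGCATGGAGAGCGT
LBprimer	61	5’pNNNNNNNGATCGTCGGACTGTAGAACTCTGAArCAGACGTGTGCTCTTCCGATCTNNNNNNN
RTprimer2	47	5’pGATCGTCGGACTGTAGAACTCTGAArCAGACGTGTGCTCTTCCGATCT
RTprimer3	21	5’AGACGTGTGCTCTTCCGATCT
Primer2F	50	5'AATGATACGGCGACCACCGAGATCTACACGTTCAGAGTTCTACAGTCCGA
Primer2R1	64	5'CAAGCAGAAGACGGCATACGAGATGCGGACGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT
Primer2R2	64	5'CAAGCAGAAGACGGCATACGAGATGATCTGGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT
Primer2R3	64	5'CAAGCAGAAGACGGCATACGAGATATTGGCGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT
Primer2R4	64	5'CAAGCAGAAGACGGCATACGAGATTACAAGGTGACTGGAGTTCAGACGTGTGCTCTTCCGATCT
122	89	5’pTTGCCTAGCAGTAGCTATTTAGTGTGATAATGGCGTTTGATAGTTTAGACACAAACACCATTGTCACACTCCACAGCTCTGCTAAGGAA
Dcr3	82	5’pGAAGGAAAAATCAGTTTTGCATAGATTTGCACAACTACATTCTTCTTGTAGTGCAACTATGCAAAACTGCAAACAAAAACTA
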