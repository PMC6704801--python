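gene_id,site_id,TM-1_NAU,TM-1_JGI,CCRI 36,Hai 7124,Hai 7124_ZJU,Xinhai 21_NAU,3-79_HAU,snp_type
Gh_A01G1265,A01_SNP_75279139,C,C,C,A,A,A,A,Interspecific
Gh_A03G0883,A03_SNP_56268582,T,T,T,C,C,C,C,Interspecific
Gh_A03G0883,A03_SNP_56268668,C,C,C,A,A,A,A,Interspecific
Gh_A03G0883,A03_SNP_56269274,G,G,G,C,C,C,C,Interspecific
Gh_A03G1469,A03_SNP_94860485,T,T,T,C,C,C,C,Interspecific
Gh_A05G1126,A05_SNP_11408439,T,T,T,G,G,G,G,Interspecific
Gh_A05G2120,A05_SNP_24158570,C,C,C,T,T,T,T,Interspecific
Gh_A05G2342,A05_SNP_28567212,A,A,A,G,G,G,G,Interspecific
Gh_A05G3179,A05_SNP_83357615,G,G,G,A,A,A,A,Interspecific
Gh_A05G3179,A05_SNP_83357788,C,C,C,G,G,G,G,Interspecific
Gh_A05G3179,A05_SNP_83358199,A,A,A,G,G,G,G,Interspecific
Gh_A12G1020,A12_SNP_61827377,A,A,A,G,G,G,G,Interspecific
Gh_A13G1399,A13_SNP_70850590,G,A,G,A,G,G,G,Interspecific
Gh_D03G1250,D03_SNP_39979124,G,G,G,T,T,T,T,Interspecific
Gh_D05G2713,D05_SNP_29061704,C,C,C,T,T,T,T,Interspecific
Gh_D05G2713,D05_SNP_29062660,A,A,A,G,G,G,G,Interspecific
Gh_D06G0184,D06_SNP_1821446,G,G,A,G,G,G,G,CCRI 36-specific
Gh_D06G0184,D06_SNP_1821486,A,A,T,A,A,A,A,CCRI 36-specific
Gh_D06G0184,D06_SNP_1821996,T,T,G,T,T,T,T,CCRI 36-specific
Gh_D11G2341,D11_SNP_45220974,C,C,C,T,T,T,T,Interspecific
Gh_D11G2347,D11_SNP_45682284,C,C,C,T,T,T,T,Interspecific
Gh_D11G2407,D11_SNP_47937585,T,T,T,G,G,T,T,Hai 7124-specific
Gh_D11G2407,D11_SNP_47937659,T,T,T,G,G,T,T,Hai 7124-specific
Gh_D12G1630,D12_SNP_47650374,C,C,C,T,T,C,C,Hai 7124-specific
Gh_D12G1630,D12_SNP_47650460,A,A,A,C,C,A,A,Hai 7124-specific
Gh_D12G1747,D12_SNP_49762738,A,A,A,G,G,G,G,Interspecific
Gh_D12G1747,D12_SNP_49763474,G,G,G,A,A,A,G,Interspecific
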