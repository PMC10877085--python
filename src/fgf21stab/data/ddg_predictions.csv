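mutation,position,wt,mut,ddg_rosetta,ddg_foldx,consensus_frequency,source_arm,msa_residues
E58P,58,E,P,-3.2,-0.44,,energy,"R,Q,D,L,N,Y,T,A,E,G,S,F,M,I"
E65P,65,E,P,-3.0,-0.71,,energy,"Y,T,S,A,G,E,H,M,R,K,D,L,P,N"
D74Y,74,D,Y,-2.4,-0.41,,energy,"D,Q,V,Y,I,F,E,G,C,R,K,N,L,T,H,A,S"
Q104M,104,Q,M,-2.1,-1.89,0.81,evolution,"Q,V,I,M,L"
A109W,109,A,W,-1.9,1.15,,energy,"K,Q,R,D,V,N,T,E,A,I,H"
D117N,117,D,N,-1.9,0.26,,energy,"E,S,M,I,H,T,L,V,N,K,Q,R,D"
Q136V,136,Q,V,-1.4,-0.32,,energy,"T,Y,H,I,M,F,S,E,W,R,Q,K,V,L"
E138L,138,E,L,-1.2,-1.23,,energy,"E,A,S,M,T,L,P,N,Q,R,K,D,C"
A139K,139,A,K,0.2,-0.66,0.50,evolution,"R,Q,K,L,N,T,A,G,H"
K150R,150,K,R,0.2,-0.44,0.52,evolution,"K,R,Q,D,P,N,T,A,S,E,G,H"
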