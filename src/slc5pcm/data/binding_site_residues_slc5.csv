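target_id,7VSI:79|MSA:88,7VSI:87|MSA:96,7VSI:95|MSA:106,7VSI:98|MSA:109,7VSI:102|MSA:113,7VSI:153|MSA:164,7VSI:157|MSA:168,7VSI:274|MSA:300,7VSI:283|MSA:309,7VSI:286|MSA:312,7VSI:287|MSA:313,7VSI:290|MSA:316,7VSI:453|MSA:481,7VSI:454|MSA:482,7VSI:457|MSA:485,7VSI:460|MSA:488
HsSLC5A1,G,T,I,F,A,T,A,L,M,L,T,Y,F,D,Q,T
RnSLC5A1,G,T,M,F,A,T,A,M,L,L,A,Y,F,D,Q,T
HsSLC5A11,G,S,V,Y,G,T,V,L,M,P,S,Y,F,I,Q,S
HsSLC5A2,G,T,V,F,A,T,V,L,L,V,S,Y,F,D,Q,S
RnSLC5A2,G,T,V,F,A,T,V,L,L,V,S,H,F,D,Q,S
HsSLC5A4,N,T,T,F,S,L,A,I,M,T,A,Y,I,H,E,S
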