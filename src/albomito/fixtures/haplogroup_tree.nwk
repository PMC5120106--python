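((((Ces2,(('J-Wa1')'A1a1a (Japanese motif)',(Rim1,(Cas1,Pav3,(Ces1,Vir2,(Vir1,Rc1)'A1a1a1a1-I')A1a1a1a1)A1a1a1a)A1a1a1)A1a1a)A1a1,(Fo2,(Ath2,Pav4,(Rim4,Tir1,Tir2,KR068634)A1a2a1)A1a2a)A1a2)A1a,((Bra)'A1b (Brazilian motif)',(Chu3,(Lam2,Ban7,Ath1)A1b1a)A1b1)A1b)A1,(Los4,(Los1,Los2,Los3,Los5)A2a)A2,(NC006817)A3)'A1''2';
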