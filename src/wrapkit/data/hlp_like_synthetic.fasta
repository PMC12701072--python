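>HLp_like_synthetic 63-residue FtF-histone-like sequence; synthetic stand-in carrying the experimentally assigned residues (A13 S14 K15 V16 K17 I20 K21 M26 T27 S28 G29 L35 L39 L42 L47 R49 S52 N53 K54 R55 T56 T57 V58 R59 T61 D62 F63) at their deposited positions, with histone-like filler elsewhere; theoretical average mass 7.1 kDa
MSKKEQNTEKALASKVKEAIKGVEDMTSGIKELILEKALAELKEAKLRREASNKRTTVRETDF
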