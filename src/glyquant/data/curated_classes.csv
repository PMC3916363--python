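composition,glycan_class,note
HexNAc2Hex6,HighMannose,secretome panel
HexNAc3Hex5,Hybrid,secretome panel
HexNAc2Hex7,HighMannose,secretome panel
HexNAc3Hex6,Hybrid,secretome panel
HexNAc4Hex4Fuc1,ComplexBiantennary,secretome panel
HexNAc4Hex5,ComplexBiantennary,secretome panel
HexNAc2Hex8,HighMannose,secretome panel
HexNAc4Hex5Fuc1,ComplexBiantennary,secretome panel
HexNAc5Hex5,Bisecting,MS/MS-confirmed bisecting GlcNAc
HexNAc2Hex9,HighMannose,secretome panel
HexNAc5Hex5Fuc1,Bisecting,MS/MS-confirmed bisecting GlcNAc
HexNAc5Hex6,Triantennary,secretome panel
HexNAc5Hex5Fuc2,ComplexBiantennary,secretome panel
HexNAc5Hex6Fuc1,Triantennary,secretome panel
HexNAc6Hex6Fuc1,Bisecting,MS/MS-confirmed bisecting GlcNAc
HexNAc6Hex7Fuc1,TetraAntennary,secretome panel
HexNAc7Hex7Fuc1,Bisecting,secretome panel
HexNAc5Hex5Fuc1NeuAc1,Bisecting,sialylated variant of bisecting parent
HexNAc5Hex5Fuc1NeuAc2,Bisecting,sialylated variant of bisecting parent
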