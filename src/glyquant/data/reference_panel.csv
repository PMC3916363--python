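observed_mz,theoretical_mz,ratio,cv_percent,change,composition,glycan_class
1419.5,1419.5,1.46,4.26,up,HexNAc2Hex6,HighMannose
1460.4,1460.5,2.05,13.44,up,HexNAc3Hex5,Hybrid
1581.5,1581.5,0.95,3.49,no,HexNAc2Hex7,HighMannose
1622.4,1622.6,1.63,12.61,up,HexNAc3Hex6,Hybrid
1647.5,1647.6,3.40,11.48,up,HexNAc4Hex4Fuc1,ComplexBiantennary
1663.6,1663.6,3.23,8.78,up,HexNAc4Hex5,ComplexBiantennary
1743.5,1743.6,1.42,4.29,up,HexNAc2Hex8,HighMannose
1809.6,1809.6,2.21,8.87,up,HexNAc4Hex5Fuc1,ComplexBiantennary
1866.6,1866.7,0.28,2.40,down,HexNAc5Hex5,Bisecting
1905.5,1905.6,2.19,10.01,up,HexNAc2Hex9,HighMannose
2012.7,2012.7,0.12,15.20,down,HexNAc5Hex5Fuc1,Bisecting
2028.6,2028.7,1.32,18.06,up,HexNAc5Hex6,Triantennary
2158.6,2158.8,0.64,17.46,down,HexNAc5Hex5Fuc2,ComplexBiantennary
2174.7,2174.8,2.21,15.99,up,HexNAc5Hex6Fuc1,Triantennary
2377.8,2377.9,0.32,9.87,down,HexNAc6Hex6Fuc1,Bisecting
2539.9,2539.9,1.78,15.90,up,HexNAc6Hex7Fuc1,TetraAntennary
2742.9,2743.0,0.73,15.35,down,HexNAc7Hex7Fuc1,Bisecting
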