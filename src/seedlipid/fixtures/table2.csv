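accession,nmr_pct,method,method_pct
soybean,4.60,butanol,13.90
F1,0.80,butanol,
112351,0.67,butanol,1.60
F2,1.09,butanol,
42819,0.77,butanol,2.50
43016,1.09,butanol,3.60
29600,1.12,butanol,2.60
45760,1.07,butanol,3.50
29579,1.02,butanol,3.70
29526,0.93,butanol,3.10
soybean,4.60,hexane_isopropanol,
F1,0.80,hexane_isopropanol,
112351,0.67,hexane_isopropanol,1.40
F2,1.09,hexane_isopropanol,
42819,0.77,hexane_isopropanol,1.70
43016,1.09,hexane_isopropanol,2.20
29600,1.12,hexane_isopropanol,1.70
45760,1.07,hexane_isopropanol,2.10
29579,1.02,hexane_isopropanol,2.60
29526,0.93,hexane_isopropanol,1.30
soybean,4.60,petroleum_ether,
F1,0.80,petroleum_ether,
112351,0.67,petroleum_ether,0.61
F2,1.09,petroleum_ether,
42819,0.77,petroleum_ether,0.67
43016,1.09,petroleum_ether,
29600,1.12,petroleum_ether,
45760,1.07,petroleum_ether,1.05
29579,1.02,petroleum_ether,0.74
29526,0.93,petroleum_ether,0.69
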