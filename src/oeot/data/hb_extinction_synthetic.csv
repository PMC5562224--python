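wavelength_nm,eps_hbo2,eps_hb
680,300.0,2407.0
690,276.0,2052.0
700,290.0,1794.0
710,314.0,1640.0
720,342.0,1520.0
730,390.0,1420.0
740,446.0,1350.0
750,518.0,1405.0
760,586.0,1549.0
770,650.0,1390.0
780,710.0,1155.0
790,756.0,960.0
798,785.0,790.0
800,796.0,762.0
810,844.0,740.0
820,916.0,710.0
840,1022.0,692.0
850,1058.0,691.0
860,1092.0,696.0
880,1154.0,726.0
900,1198.0,762.0
910,1216.0,780.0
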