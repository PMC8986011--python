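habitat,area_m2
Cocoa Crop,59940
Riparian Forest,450552
Star Grass Paddock,54968
King Grass Crop,13245
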