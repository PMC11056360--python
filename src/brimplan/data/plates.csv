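manufacturer,d,e1,e2,e3,e4
Wego,12.1,19.1,31.1,43.3,55.2
Trauson,12.1,19.2,31.2,43.5,55.4
Naton,12.2,19.2,31.4,43.2,55.3
Synthes,12.5,19.8,32.6,45.2,57.8
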