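{
 "transform": "log10_floor1",
 "polygon": [[3.0, 1.0], [6.5, 1.6], [6.5, 5.5], [3.0, 4.9]],
 "lna_hna_threshold": 4.0
}
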