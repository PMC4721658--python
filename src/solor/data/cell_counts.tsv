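gene	mean	sd
Olfr19	1493	143
Olfr49	148	85
Olfr266	421	168
Olfr267	130	87
Olfr370	232	125
Olfr371	2076	221
Olfr466	832	11
Olfr1402	538	214
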