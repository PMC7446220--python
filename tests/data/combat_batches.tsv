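sample_id	batch
S00	b1
S01	b1
S02	b1
S03	b1
S04	b1
S05	b1
S06	b2
S07	b2
S08	b2
S09	b2
S10	b2
S11	b2
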