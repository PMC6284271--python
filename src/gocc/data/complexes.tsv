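name	go_id
eIF3 complex	GO:0005852
26S proteasome	GO:0000502
exosome complex
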