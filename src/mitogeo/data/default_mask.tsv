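kind	value
position	16182
position	16183
position	16519
insertion	309
insertion	315
insertion	573
insertion	16193
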