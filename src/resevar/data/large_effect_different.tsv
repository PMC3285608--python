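group	atg_change	premature_stop	stop_change
different	2	5	3
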