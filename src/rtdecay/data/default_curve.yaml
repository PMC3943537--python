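family: effective_gaussian
params:
- 0.021268847103907355
domain:
- 0.041666666666666664
- 0.5
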