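(variant3:1,(variant2:1,variant4:1)variant1:1)inferred1;
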