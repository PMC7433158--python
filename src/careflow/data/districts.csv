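name,population_2001,population_2011
4th Municipal Community,92310,85629
5th Municipal Community,105539,98665
6th Municipal Community,162366,130582
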