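layer,params,flops_millions,peak_ram_kb
Input,0,0,0.75
Conv1D-1,96,0.82,12.4
MaxPooling,0,0.04,6.2
Conv1D-2,1568,3.12,28.8
Flatten,0,0.26,14.4
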