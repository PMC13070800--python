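manual_class,predicted_class,count
PR,PR,3
PR,SD,1
SD,PR,0
SD,SD,10
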