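reference,chilensis,T/E/G,unassigned
trossulus,0,50,0
edulis,0,50,0
galloprovincialis,2,64,0
chilensis,92,0,0
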