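reference,trossulus,edulis,galloprovincialis,chilensis,unassigned
trossulus,35,11,0,0,0
edulis,0,31,1,18,0
galloprovincialis,0,21,44,0,0
chilensis,0,57,1,34,0
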