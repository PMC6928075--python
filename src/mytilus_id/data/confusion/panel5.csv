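reference,trossulus,edulis,galloprovincialis,chilensis,unassigned
trossulus,50,0,0,0,0
edulis,0,50,0,0,0
galloprovincialis,0,0,66,0,0
chilensis,0,0,0,92,0
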