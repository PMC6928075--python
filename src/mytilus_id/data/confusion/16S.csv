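reference,trossulus,edulis,galloprovincialis,chilensis,unassigned
trossulus,46,0,0,0,0
edulis,0,49,0,1,0
galloprovincialis,0,59,5,2,0
chilensis,0,0,0,91,0
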