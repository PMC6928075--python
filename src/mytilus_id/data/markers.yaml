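# Default PCR-RFLP marker registry for Mytilus specimen identification.
#
# Me15-16 and COI alleles are defined by amplicon length + restriction cut
# position (both derivable from the published fragment pairs); ITS and 16S
# haplotypes are defined directly by their fragment-size patterns because cut
# positions for those amplicons are not published.  The two 16S haplotypes
# first observed in this marker system (one trossulus-like missing the NheI
# site, one galloprovincialis-like with EcoRV present and NheI absent) are
# registered as site-presence descriptors without committed fragment sizes;
# they carry no diagnostic species and enter only frequency-based assignment.
markers:
  - name: Me15-16
    inheritance: nuclear
    enzymes: [AciI]
    diagnostic_level: fully
    tolerance_bp: 4
    alleles:
      - label: 180-E
        amplicon_length: 180
        cut_positions: []
      - label: 168-T
        amplicon_length: 168
        cut_positions: []
      - label: 126-G
        amplicon_length: 126
        cut_positions: [77]
      - label: 126-Ch
        amplicon_length: 126
        cut_positions: []
    diagnostic_map:
      180-E: edulis
      168-T: trossulus
      126-G: galloprovincialis
      126-Ch: chilensis

  - name: ITS
    inheritance: nuclear
    enzymes: [HhaI]
    diagnostic_level: semi
    tolerance_bp: 2
    alleles:
      - label: EGCh
        fragments: [435, 179, 155, 144]
      - label: tros
        fragments: [237, 192, 183, 156, 145]
    diagnostic_map:
      EGCh: E/G/Ch
      tros: trossulus

  - name: COI
    inheritance: mito
    enzymes: [XbaI]
    diagnostic_level: fully
    tolerance_bp: 4
    alleles:
      - label: uncut
        amplicon_length: 233
        cut_positions: []
      - label: chilensis-cut
        amplicon_length: 233
        cut_positions: [134]
    diagnostic_map:
      chilensis-cut: chilensis
      uncut: T/E/G

  - name: 16S
    inheritance: mito
    enzymes: [EcoRV, NheI, SpeI]
    diagnostic_level: semi
    tolerance_bp: 4
    open_registry: true
    alleles:
      - label: edulis
        fragments: [342, 85, 82, 28]
      - label: trossulus
        fragments: [379, 85, 82]
      - label: galloprovincialis
        fragments: [342, 195]
      - label: chilensis
        fragments: [342, 167, 28]
      - label: tros-new
        sites: {EcoRV: absent, NheI: absent, SpeI: present}
      - label: gallo-new
        sites: {EcoRV: present, NheI: absent, SpeI: present}
    diagnostic_map:
      edulis: edulis
      trossulus: trossulus
      galloprovincialis: galloprovincialis
      chilensis: chilensis

  - name: mac-1
    inheritance: nuclear
    enzymes: []
    diagnostic_level: semi
    tolerance_bp: 2
    open_registry: true
    size_range: [164, 494]
    alleles:
      - {label: "164", amplicon_length: 164, cut_positions: []}
      - {label: "180", amplicon_length: 180, cut_positions: []}
      - {label: "211", amplicon_length: 211, cut_positions: []}
      - {label: "230", amplicon_length: 230, cut_positions: []}
      - {label: "255", amplicon_length: 255, cut_positions: []}
      - {label: "266", amplicon_length: 266, cut_positions: []}
      - {label: "298", amplicon_length: 298, cut_positions: []}
      - {label: "303", amplicon_length: 303, cut_positions: []}
      - {label: "328", amplicon_length: 328, cut_positions: []}
      - {label: "347", amplicon_length: 347, cut_positions: []}
      - {label: "376", amplicon_length: 376, cut_positions: []}
      - {label: "402", amplicon_length: 402, cut_positions: []}
      - {label: "487", amplicon_length: 487, cut_positions: []}
      - {label: "494", amplicon_length: 494, cut_positions: []}
    diagnostic_map: {}
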