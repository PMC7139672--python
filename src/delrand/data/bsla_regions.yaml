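# Structurally variable regions of mature BSLA targeted for
# deletion/randomization (mature numbering, inclusive bounds).
# Lib 4 uses an explicit deleted-block override: its reported deleted pair
# (92-93) is one position right of the default middle rule.
regions:
  - name: "Lib 1"
    start: 10
    end: 18
  - name: "Lib 2"
    start: 29
    end: 34
  - name: "Lib 3"
    start: 40
    end: 46
  - name: "Lib 4"
    start: 90
    end: 94
    deleted_override: [92, 93]
  - name: "Lib 5"
    start: 104
    end: 113
  - name: "Lib 6"
    start: 114
    end: 123
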