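{
  "_comment": "Illustrative supergroup definitions for merging small areas before comparison with expert cell-count tables. The 'core and belt' auditory grouping uses the standard marmoset auditory core/belt abbreviations; edit to match the nomenclature of the reference dataset in use.",
  "core and belt": ["AuA1", "AuR", "AuRT", "AuAL", "AuML", "AuCM", "AuCPB", "AuRPB", "AuRTM", "AuRTL"]
}
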