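{
 "library_1": "N5",
 "library_2": "N6",
 "total_raw_reads": {
  "N5": 38399972,
  "N6": 23689204
 },
 "total_clean_reads": {
  "N5": 2260210,
  "N6": 2174640
 },
 "description": "Counts and RPKM of 61 canonical miRNAs in the pre-metamorphic (N5) and metamorphic (N6) nymphal small-RNA libraries of Blattella germanica."
}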