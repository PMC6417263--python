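code,label,suitability
901,Cemeteries,1
902,Landfill sites,0.2
903,Garden centres,1
904,Gardens,1
905,Zoological gardens,1
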