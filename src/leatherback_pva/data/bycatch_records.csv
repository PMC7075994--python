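source,gear,interactions,mortality,period_years
regional_compilation,longline,132,,4.54
regional_compilation,gillnet,176,,4.54
regional_compilation,driftnet,100,,4.54
regional_compilation,other,32,,4.54
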