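use,pressure,weight,distance_m
fishery,abrasion,0.8,0
fishery,noise,0.3,1000
transport,noise,0.9,2000
transport,litter,0.6,5000
aquaculture,organic_enrichment,0.7,1000
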