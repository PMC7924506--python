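pressure,env,sensitivity
abrasion,seagrass,2.5
abrasion,mammals,0.0
noise,mammals,2.0
noise,seagrass,0.2
litter,mammals,0.8
litter,seagrass,0.3
organic_enrichment,seagrass,1.5
organic_enrichment,mammals,0.5
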