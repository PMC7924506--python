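use,vertical_domain,spatial_domain,temporal_domain,mobility
fishery,seabed;water_column,large,year_round,mobile
transport,surface;water_column,large,year_round,mobile
aquaculture,water_column;seabed,local,year_round,fixed
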