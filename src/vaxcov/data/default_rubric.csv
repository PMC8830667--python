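barrier_id,variant,level,score
vaccine_schedule,default,Low,0.00
vaccine_schedule,default,Medium-Low,0.25
vaccine_schedule,default,Medium,0.50
vaccine_schedule,default,Medium-High,0.75
vaccine_schedule,default,High,1.00
temperature_storage,default,Low,0.00
temperature_storage,default,Medium-Low,0.25
temperature_storage,default,Medium,0.50
temperature_storage,default,Medium-High,0.80
temperature_storage,default,High,1.00
administration,default,Low,0.00
administration,default,Medium-Low,0.40
administration,default,Medium,0.70
administration,default,Medium-High,0.90
administration,default,High,1.00
acceptability,generic,Low,0.00
acceptability,generic,Medium-Low,0.30
acceptability,generic,Medium,0.40
acceptability,generic,Medium-High,0.70
acceptability,generic,High,1.00
acceptability,pork_product,Low,0.00
acceptability,pork_product,Medium-Low,0.75
acceptability,pork_product,Medium,0.90
acceptability,pork_product,Medium-High,0.95
acceptability,pork_product,High,1.00
doses_per_container,default,Low,0.00
doses_per_container,default,Medium-Low,0.20
doses_per_container,default,Medium,0.40
doses_per_container,default,Medium-High,0.75
doses_per_container,default,High,1.00
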