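# unitops program file v1
program "FDG (one-pot)"
reagent 1.2 Eluent volume=0.8 desc="1 mg K2CO3 in 0.3 mL water; 10 mg K222 in 0.5 mL acetonitrile"
reagent 1.3 MeCN-1 volume=1 desc="1.0 mL acetonitrile"
reagent 1.5 MeCN-2 volume=1 desc="1.0 mL acetonitrile"
reagent 1.6 "Mannose triflate" volume=1 desc="30 mg mannose triflate dissolved in 1.0 mL acetonitrile"
reagent 1.7 HCl volume=1 desc="1.0 mL of 1 N HCl"
reagent 1.8 Water-1 volume=2.5 desc="2.5 mL water"
reagent 1.9 Water-2 volume=2.5 desc="2.5 mL water"
op INITIALIZE
op TRAPF18 reactor=1 cyclotron_flag=false duration_s=120 pressure_psi=3
op ELUTEF18 reactor=1 reagent_name=Eluent duration_s=120 pressure_psi=3
op EVAPORATE reactor=1 evaporation_temp_C=110 evaporation_pressure_psi=15 duration_s=300
op ELUTEF18 reactor=1 reagent_name=MeCN-1 duration_s=90 pressure_psi=3
op EVAPORATE reactor=1 evaporation_temp_C=110 evaporation_pressure_psi=10 duration_s=120
op ADD reagent_name=MeCN-2 reactor=1 delivery_position=1
op EVAPORATE reactor=1 evaporation_temp_C=110 evaporation_pressure_psi=10 duration_s=120 final_temp_C=30
op ADD reagent_name="Mannose triflate" reactor=1 delivery_position=1
op REACT reactor=1 reaction_temp_C=130 reaction_position=1 duration_s=300 final_temp_C=35 cool_delay_s=120
op EVAPORATE reactor=1 evaporation_temp_C=110 evaporation_pressure_psi=10 duration_s=120
op ADD reagent_name=HCl reactor=1 delivery_position=1
op REACT reactor=1 reaction_temp_C=130 reaction_position=1 duration_s=300 final_temp_C=35 cool_delay_s=120
op TRANSFER source_reactor=1 target_reactor=1 mode=Elute pressure_psi=10 duration_s=30
op ADD reagent_name=Water-1 reactor=1 delivery_position=1
op TRANSFER source_reactor=1 target_reactor=1 mode=Elute pressure_psi=10 duration_s=30
op ADD reagent_name=Water-2 reactor=1 delivery_position=1
op TRANSFER source_reactor=1 target_reactor=1 mode=Elute pressure_psi=10 duration_s=45
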