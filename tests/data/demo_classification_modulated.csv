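unit_id,label,responsive,direction,supra_bins
modulated_u000,CS_ON,True,excited,0;2;3;4
modulated_u000,FREEZE_ON,False,none,
modulated_u000,FREEZE_OFF,False,none,
modulated_u001,CS_ON,True,excited,0;1;2;3;4
modulated_u001,FREEZE_ON,False,none,
modulated_u001,FREEZE_OFF,False,none,
modulated_u002,CS_ON,True,excited,1;3;4
modulated_u002,FREEZE_ON,False,none,
modulated_u002,FREEZE_OFF,False,none,
modulated_u003,CS_ON,True,excited,0;1;3
modulated_u003,FREEZE_ON,False,none,
modulated_u003,FREEZE_OFF,False,none,
modulated_u004,CS_ON,True,excited,2;3
modulated_u004,FREEZE_ON,True,excited,1;4
modulated_u004,FREEZE_OFF,False,none,
modulated_u005,CS_ON,False,none,
modulated_u005,FREEZE_ON,True,excited,2;4
modulated_u005,FREEZE_OFF,False,none,
modulated_u006,CS_ON,False,none,
modulated_u006,FREEZE_ON,False,none,
modulated_u006,FREEZE_OFF,False,none,
modulated_u007,CS_ON,False,none,
modulated_u007,FREEZE_ON,False,none,
modulated_u007,FREEZE_OFF,False,none,
modulated_u008,CS_ON,False,none,
modulated_u008,FREEZE_ON,False,none,
modulated_u008,FREEZE_OFF,True,excited,0;1
modulated_u009,CS_ON,False,none,
modulated_u009,FREEZE_ON,False,none,
modulated_u009,FREEZE_OFF,False,none,
modulated_u010,CS_ON,False,none,
modulated_u010,FREEZE_ON,True,excited,1;3
modulated_u010,FREEZE_OFF,False,none,
modulated_u011,CS_ON,True,inhibited,0;4
modulated_u011,FREEZE_ON,False,none,
modulated_u011,FREEZE_OFF,False,none,
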