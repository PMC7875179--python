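patient_id,state,response_channel,response_week,personalization,outreach,exclusion_reason,referral,nonreferral_reason,detection_week
D001,NO_CONTACT,NONE,,patient_name,false,none,NA,,0
D002,NO_CONTACT,NONE,,patient_name,false,none,NA,,0
D003,RESPONDED,EMAIL1,0,patient_name,true,moved_out,NA,,0
D004,RESPONDED,EMAIL1,0,patient_name,true,none,REFERRED,,0
D005,RESPONDED,EMAIL1,0,patient_name,true,none,REFERRED,,0
D006,RESPONDED,EMAIL1,0,patient_name,true,none,REFERRED,,0
D007,RESPONDED,EMAIL1,0,patient_name,true,none,REFERRED,,0
D008,RESPONDED,EMAIL1,0,patient_name,true,moved_out,NA,,0
D009,RESPONDED,EMAIL1,0,patient_name,true,none,REFERRED,,0
D010,RESPONDED,EMAIL1,0,patient_name,true,none,REFERRED,,0
D011,RESPONDED,EMAIL1,0,patient_name,true,none,REFERRED,,0
D012,RESPONDED,EMAIL1,0,patient_name,true,none,REFERRED,,0
D013,RESPONDED,EMAIL1,0,patient_name,true,moved_out,NA,,0
D014,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D015,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D016,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D017,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D018,RESPONDED,EMAIL1,0,patient_name,false,moved_out,NA,,0
D019,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D020,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D021,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D022,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D023,RESPONDED,EMAIL1,0,patient_name,false,moved_out,NA,,0
D024,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D025,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D026,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D027,RESPONDED,EMAIL1,0,patient_name,false,none,REFERRED,,0
D028,RESPONDED,EMAIL1,0,trust_id,false,moved_out,NA,,0
D029,RESPONDED,EMAIL1,0,trust_id,false,none,REFERRED,,0
D030,RESPONDED,EMAIL1,0,trust_id,false,none,REFERRED,,0
D031,RESPONDED,EMAIL1,0,trust_id,false,none,REFERRED,,0
D032,RESPONDED,EMAIL1,0,trust_id,false,none,REFERRED,,0
D033,RESPONDED,EMAIL1,0,trust_id,false,moved_out,NA,,0
D034,RESPONDED,EMAIL1,0,trust_id,false,none,REFERRED,,0
D035,RESPONDED,EMAIL1,0,trust_id,false,none,REFERRED,,0
D036,RESPONDED,EMAIL2,1,patient_name,true,none,REFERRED,,0
D037,RESPONDED,EMAIL2,1,patient_name,true,none,REFERRED,,0
D038,RESPONDED,EMAIL2,1,patient_name,true,moved_out,NA,,0
D039,RESPONDED,EMAIL2,1,patient_name,true,none,REFERRED,,0
D040,RESPONDED,EMAIL2,1,patient_name,true,none,REFERRED,,0
D041,RESPONDED,EMAIL2,1,patient_name,true,none,REFERRED,,0
D042,RESPONDED,EMAIL2,1,patient_name,true,none,REFERRED,,0
D043,RESPONDED,EMAIL2,1,patient_name,false,moved_out,NA,,0
D044,RESPONDED,EMAIL2,1,patient_name,false,none,REFERRED,,0
D045,RESPONDED,EMAIL2,1,patient_name,false,none,REFERRED,,0
D046,RESPONDED,EMAIL2,1,patient_name,false,none,REFERRED,,0
D047,RESPONDED,EMAIL2,1,patient_name,false,none,REFERRED,,0
D048,RESPONDED,EMAIL2,1,patient_name,false,moved_out,NA,,0
D049,RESPONDED,EMAIL2,1,patient_name,false,none,REFERRED,,0
D050,RESPONDED,EMAIL2,1,trust_id,false,none,REFERRED,,0
D051,RESPONDED,EMAIL2,1,trust_id,false,none,REFERRED,,0
D052,RESPONDED,EMAIL2,1,trust_id,false,none,NOT_REFERRED,acute_phase,0
D053,RESPONDED,EMAIL2,1,trust_id,false,organic_condition,NA,,0
D054,RESPONDED,EMAIL2,1,trust_id,false,none,NOT_REFERRED,acute_phase,0
D055,RESPONDED,EMAIL2,1,trust_id,false,none,NOT_REFERRED,acute_phase,0
D056,RESPONDED,EMAIL3,2,patient_name,true,none,NOT_REFERRED,acute_phase,0
D057,RESPONDED,EMAIL3,2,patient_name,true,none,NOT_REFERRED,acute_phase,0
D058,RESPONDED,EMAIL3,2,patient_name,false,organic_condition,NA,,0
D059,RESPONDED,EMAIL3,2,patient_name,false,none,NOT_REFERRED,acute_phase,0
D060,RESPONDED,EMAIL3,2,patient_name,false,none,NOT_REFERRED,acute_phase,0
D061,RESPONDED,EMAIL3,2,trust_id,false,none,NOT_REFERRED,acute_phase,0
D062,RESPONDED,PHONE,3,patient_name,true,none,NOT_REFERRED,acute_phase,0
D063,RESPONDED,PHONE,3,patient_name,true,organic_condition,NA,,0
D064,RESPONDED,PHONE,3,patient_name,true,none,NOT_REFERRED,acute_phase,0
D065,RESPONDED,PHONE,3,patient_name,true,none,NOT_REFERRED,acute_phase,0
D066,RESPONDED,PHONE,3,patient_name,true,none,NOT_REFERRED,acute_phase,0
D067,RESPONDED,PHONE,3,patient_name,true,none,NOT_REFERRED,acute_phase,0
D068,RESPONDED,PHONE,3,patient_name,true,organic_condition,NA,,0
D069,RESPONDED,PHONE,3,patient_name,true,none,NOT_REFERRED,acute_phase,0
D070,RESPONDED,PHONE,3,patient_name,true,none,NOT_REFERRED,acute_phase,0
D071,RESPONDED,PHONE,3,patient_name,false,none,NOT_REFERRED,acute_phase,0
D072,RESPONDED,PHONE,3,patient_name,false,none,NOT_REFERRED,acute_phase,0
D073,RESPONDED,PHONE,3,patient_name,false,language,NA,,0
D074,RESPONDED,PHONE,3,patient_name,false,none,NOT_REFERRED,acute_phase,0
D075,RESPONDED,PHONE,3,patient_name,false,none,NOT_REFERRED,acute_phase,0
D076,RESPONDED,PHONE,3,patient_name,false,none,NOT_REFERRED,acute_phase,0
D077,RESPONDED,PHONE,3,patient_name,false,none,NOT_REFERRED,acute_phase,0
D078,RESPONDED,PHONE,3,patient_name,false,language,NA,,0
D079,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,acute_phase,0
D080,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D081,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D082,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D083,RESPONDED,PHONE,3,trust_id,false,psychosis_from_collateral,NA,,0
D084,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D085,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D086,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D087,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D088,RESPONDED,PHONE,3,trust_id,false,declined,NA,,0
D089,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D090,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D091,RESPONDED,PHONE,3,trust_id,false,none,NOT_REFERRED,other,0
D092,NO_RESPONSE,NONE,,patient_name,true,none,NA,,0
D093,NO_RESPONSE,NONE,,patient_name,true,none,NA,,0
D094,NO_RESPONSE,NONE,,patient_name,true,none,NA,,0
D095,NO_RESPONSE,NONE,,patient_name,true,none,NA,,0
D096,NO_RESPONSE,NONE,,patient_name,true,none,NA,,0
D097,NO_RESPONSE,NONE,,patient_name,false,none,NA,,0
D098,NO_RESPONSE,NONE,,patient_name,false,none,NA,,0
D099,NO_RESPONSE,NONE,,patient_name,false,none,NA,,0
D100,NO_RESPONSE,NONE,,patient_name,false,none,NA,,0
D101,NO_RESPONSE,NONE,,patient_name,false,none,NA,,0
D102,NO_RESPONSE,NONE,,patient_name,false,none,NA,,0
D103,NO_RESPONSE,NONE,,patient_name,false,none,NA,,0
D104,NO_RESPONSE,NONE,,patient_name,false,none,NA,,0
D105,NO_RESPONSE,NONE,,patient_name,false,none,NA,,0
D106,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D107,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D108,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D109,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D110,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D111,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D112,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D113,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D114,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D115,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D116,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
D117,NO_RESPONSE,NONE,,trust_id,false,none,NA,,0
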