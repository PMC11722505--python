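note_id,note_type,note_datetime,text
ex-last-night,TRIAGE,2000-01-06 10:00,"c/o cp which began last night at 9 pm while he was watching TV, denies being diaphoretic or nausea. has taken 6 nitro since last night. has had 6 stents in past. ekg in triage"
ex-dotted-time,HP,2000-01-05 10:00,66 y/o male presents to SMH ED with complains of chest pain since morning 4.45 am
ex-woke,TRIAGE,2000-01-05 10:15,"He was in his usual state of health until approx 3AM today, when he says he woke and had severe chest discomfort/pressure"
ex-military,TRIAGE,2000-01-05 09:00,C/o midsternal chest pain radiating to right arm and neck since 0530 today
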