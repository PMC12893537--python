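# alias	standard	class
fondaparinux	fondaparinux	other_anticoagulant
fondaparinux sodium	fondaparinux	other_anticoagulant
arixtra	fondaparinux	other_anticoagulant
enoxaparin	enoxaparin	heparin_lmwh
enoxaparin sodium	enoxaparin	heparin_lmwh
lovenox	enoxaparin	heparin_lmwh
clexane	enoxaparin	heparin_lmwh
heparin	heparin	heparin_lmwh
heparin sodium	heparin	heparin_lmwh
unfractionated heparin	heparin	heparin_lmwh
ufh	heparin	heparin_lmwh
dalteparin	dalteparin	heparin_lmwh
dalteparin sodium	dalteparin	heparin_lmwh
tinzaparin	tinzaparin	heparin_lmwh
warfarin	warfarin	warfarin
warfarin sodium	warfarin	warfarin
coumadin	warfarin	warfarin
apixaban	apixaban	doac
eliquis	apixaban	doac
rivaroxaban	rivaroxaban	doac
xarelto	rivaroxaban	doac
dabigatran	dabigatran	doac
dabigatran etexilate	dabigatran	doac
pradaxa	dabigatran	doac
edoxaban	edoxaban	doac
savaysa	edoxaban	doac
argatroban	argatroban	other_anticoagulant
bivalirudin	bivalirudin	other_anticoagulant
aspirin	aspirin	antiplatelet
acetylsalicylic acid	aspirin	antiplatelet
clopidogrel	clopidogrel	antiplatelet
plavix	clopidogrel	antiplatelet
ticagrelor	ticagrelor	antiplatelet
brilinta	ticagrelor	antiplatelet
prasugrel	prasugrel	antiplatelet
acetaminophen	acetaminophen	none
paracetamol	acetaminophen	none
metformin	metformin	none
omeprazole	omeprazole	none
lisinopril	lisinopril	none
atorvastatin	atorvastatin	none
amoxicillin	amoxicillin	none
furosemide	furosemide	none
metoprolol	metoprolol	none
amlodipine	amlodipine	none
pantoprazole	pantoprazole	none
levothyroxine	levothyroxine	none
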