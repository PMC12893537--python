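# Toy PT -> primary SOC vocabulary (synthetic stand-in for the licensed
# MedDRA distribution; covers the 25 standard system organ classes).
haematoma	vascular disorders
haemorrhage	vascular disorders
haemorrhagic shock	vascular disorders
hypotension	vascular disorders
deep vein thrombosis	vascular disorders
embolism	vascular disorders
anaemia	blood and lymphatic system disorders
heparin-induced thrombocytopenia	blood and lymphatic system disorders
thrombosis with thrombocytopenia syndrome	blood and lymphatic system disorders
thrombocytopenia	blood and lymphatic system disorders
eosinophilia	blood and lymphatic system disorders
thrombocytosis	blood and lymphatic system disorders
leukocytosis	blood and lymphatic system disorders
coagulopathy	blood and lymphatic system disorders
coagulation factor x level abnormal	investigations
haemoglobin decreased	investigations
platelet count decreased	investigations
international normalised ratio increased	investigations
haematuria	renal and urinary disorders
renal failure	renal and urinary disorders
hepatic function abnormal	hepatobiliary disorders
abortion spontaneous	pregnancy, puerperium and perinatal conditions
gastrointestinal haemorrhage	gastrointestinal disorders
melaena	gastrointestinal disorders
nausea	gastrointestinal disorders
rectal haemorrhage	gastrointestinal disorders
incision site haematoma	injury, poisoning and procedural complications
post procedural haemorrhage	injury, poisoning and procedural complications
fall	injury, poisoning and procedural complications
pulmonary embolism	respiratory, thoracic and mediastinal disorders
epistaxis	respiratory, thoracic and mediastinal disorders
dyspnoea	respiratory, thoracic and mediastinal disorders
myocardial infarction	cardiac disorders
cardiac arrest	cardiac disorders
headache	nervous system disorders
dizziness	nervous system disorders
haemorrhage intracranial	nervous system disorders
hip arthroplasty	surgical and medical procedures
rash	skin and subcutaneous tissue disorders
ecchymosis	skin and subcutaneous tissue disorders
muscle haemorrhage	musculoskeletal and connective tissue disorders
arthralgia	musculoskeletal and connective tissue disorders
injection site haematoma	general disorders and administration site conditions
pyrexia	general disorders and administration site conditions
fatigue	general disorders and administration site conditions
heart disease congenital	congenital, familial and genetic disorders
hypothyroidism	endocrine disorders
menorrhagia	reproductive system and breast disorders
neoplasm malignant	neoplasms benign, malignant and unspecified (incl cysts and polyps)
decreased appetite	metabolism and nutrition disorders
anaphylactic reaction	immune system disorders
antiphospholipid syndrome	immune system disorders
conjunctival haemorrhage	eye disorders
pneumonia	infections and infestations
sepsis	infections and infestations
vertigo	ear and labyrinth disorders
insomnia	psychiatric disorders
anxiety	psychiatric disorders
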