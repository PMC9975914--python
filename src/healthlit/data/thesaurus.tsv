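# Thesaurus: headword<TAB>pattern1|pattern2<TAB>alt1|alt2<TAB>source
# Starter subset of everyday-word alternatives for public-health jargon.
utilize	utilize|utilise|utilizes|utilized|utilizing	use	everyday-words
physician	physician|physicians	doctor	everyday-words
hypertension	hypertension	high blood pressure	everyday-words
adverse	adverse	harmful|bad	everyday-words
administer	administer|administered|administering	give	everyday-words
cease	cease|ceases|ceased|ceasing	stop	everyday-words
commence	commence|commences|commenced|commencing	start|begin	everyday-words
prior to	prior to	before	everyday-words
in the event of	in the event of	if	everyday-words
obtain	obtain|obtains|obtained|obtaining	get	everyday-words
assist	assist|assists|assisted|assisting	help	everyday-words
sufficient	sufficient	enough	everyday-words
immunization	immunization|immunisation|immunizations	vaccine|shot	everyday-words
analgesic	analgesic|analgesics	pain reliever	everyday-words
cardiac	cardiac	heart	everyday-words
pulmonary	pulmonary	lung	everyday-words
renal	renal	kidney	everyday-words
hepatic	hepatic	liver	everyday-words
edema	edema|oedema	swelling	everyday-words
hemorrhage	hemorrhage|haemorrhage	heavy bleeding	everyday-words
lesion	lesion|lesions	sore|wound	everyday-words
malignant	malignant	cancerous	everyday-words
benign	benign	not cancer	everyday-words
monitor	monitor|monitored|monitoring	keep track of|watch	everyday-words
adequate	adequate	enough	everyday-words
approximately	approximately	about	everyday-words
consume	consume|consumed|consuming	eat|drink	everyday-words
terminate	terminate|terminated|terminating	end|stop	everyday-words
initiate	initiate|initiated|initiating	start	everyday-words
additional	additional	more|extra	everyday-words
assistance	assistance	help	everyday-words
notify	notify|notified|notifying	tell	everyday-words
purchase	purchase|purchased|purchasing	buy	everyday-words
demonstrate	demonstrate|demonstrated|demonstrating	show	everyday-words
fatigue	fatigue	tiredness	everyday-words
febrile	febrile	feverish	everyday-words
hyperglycemia	hyperglycemia|hyperglycaemia	high blood sugar	everyday-words
hypoglycemia	hypoglycemia|hypoglycaemia	low blood sugar	everyday-words
contusion	contusion|contusions	bruise	everyday-words
laceration	laceration|lacerations	cut	everyday-words
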