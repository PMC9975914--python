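# Person-centered language: pattern<TAB>suggestion<TAB>condition<TAB>rationale
# Starter set distilled from peak-body language position statements.
sufferer	a person living with the condition	general	avoids defining people by their condition
sufferers	people living with the condition	general	avoids defining people by their condition
suffers from	lives with	general	reduces blame and pity framing
suffering from	living with	general	reduces blame and pity framing
afflicted with	living with	general	reduces blame and pity framing
victim	person living with the condition	general	avoids casting people as passive victims
diabetic	person with diabetes	diabetes	person-first wording; the person is not the disease
diabetics	people with diabetes	diabetes	person-first wording; the person is not the disease
demented	person living with dementia	dementia	avoids stigmatizing labels
senile	person living with dementia	dementia	avoids outdated, stigmatizing labels
dementia sufferer	person living with dementia	dementia	avoids defining people by their condition
cancer victim	person living with cancer	cancer	avoids casting people as passive victims
battling cancer	living with cancer	cancer	avoids war metaphors that imply winners and losers
schizophrenic	person living with schizophrenia	mental_health	person-first wording
addict	person with a substance use disorder	mental_health	reduces stigma around substance use
drug abuser	person who uses drugs	mental_health	reduces stigma around substance use
committed suicide	died by suicide	mental_health	avoids framing suicide as a crime
mentally ill	person living with a mental health condition	mental_health	person-first wording
chronic pain sufferer	person living with chronic pain	chronic_pain	avoids defining people by their condition
wheelchair-bound	person who uses a wheelchair	general	a wheelchair enables rather than confines
confined to a wheelchair	uses a wheelchair	general	a wheelchair enables rather than confines
handicapped	person with disability	general	avoids outdated labels
the disabled	people with disability	general	avoids reducing people to a label
noncompliant	has not taken the medicine as prescribed	general	describes behaviour without blame
non-compliant	has not taken the medicine as prescribed	general	describes behaviour without blame
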