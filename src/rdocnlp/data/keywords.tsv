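domain	keyword
negative_valence	fear
negative_valence	panic
negative_valence	panic attacks
negative_valence	worry
negative_valence	anxiety
negative_valence	anxious
negative_valence	chronic stress
negative_valence	stress
negative_valence	avoidance
negative_valence	grief
negative_valence	distress
positive_valence	anhedonia
positive_valence	reward
positive_valence	motivation
positive_valence	craving
positive_valence	alcohol craving
positive_valence	alcohol
positive_valence	substance craving
positive_valence	pleasure
positive_valence	apathy
cognitive	attention
cognitive	memory
cognitive	concentration
cognitive	planning
cognitive	forgetful
cognitive	distractible
cognitive	decision making
cognitive	confusion
arousal_regulatory	sleep
arousal_regulatory	insomnia
arousal_regulatory	hyperarousal
arousal_regulatory	startle
arousal_regulatory	nightmares
arousal_regulatory	nervousness
arousal_regulatory	restless
arousal_regulatory	fatigue
arousal_regulatory	stress
social_processes	shame
social_processes	guilt
social_processes	attachment
social_processes	isolation
social_processes	social withdrawal
social_processes	distrust
social_processes	aggression
social_processes	paranoid
sensorimotor	tremor
sensorimotor	gait
sensorimotor	coordination
sensorimotor	psychomotor
sensorimotor	balance
sensorimotor	muscle tension
sensorimotor	slowed movements
sensorimotor	clumsiness
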