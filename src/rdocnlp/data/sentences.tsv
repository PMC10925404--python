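entry_id	domain	text
1	negative_valence	Patient reports intense fear when reminded of the trauma.
2	negative_valence	She describes frequent panic attacks occurring several times a week.
3	negative_valence	He endorses constant worry about the safety of his family.
4	negative_valence	Longstanding anxiety has worsened since the accident.
5	negative_valence	The patient remains anxious in crowded public places.
6	negative_valence	Ongoing chronic stress at work is contributing to his symptoms.
7	negative_valence	Marked avoidance of trauma reminders continues to limit daily activities.
8	negative_valence	She is struggling with unresolved grief following the loss of her spouse.
9	negative_valence	Significant emotional distress was evident throughout the interview.
10	negative_valence	Sudden episodes of panic occur without a clear trigger.
11	positive_valence	Patient endorses anhedonia with little interest in previously enjoyed hobbies.
12	positive_valence	He shows diminished response to reward and rarely feels satisfaction.
13	positive_valence	Motivation to engage in treatment goals remains very low.
14	positive_valence	She reports strong craving for alcohol on most evenings.
15	positive_valence	Persistent alcohol craving has led to repeated relapses this year.
16	positive_valence	He continues to drink alcohol daily despite medical advice.
17	positive_valence	Intense substance craving is triggered by contact with former acquaintances.
18	positive_valence	Patient derives little pleasure from social or recreational activities.
19	positive_valence	Marked apathy has replaced his usual engagement with family life.
20	positive_valence	Reward seeking behavior has increased alongside risky spending.
21	cognitive	Patient has difficulty sustaining attention during routine tasks.
22	cognitive	She reports worsening memory for recent conversations and appointments.
23	cognitive	Poor concentration interferes with his ability to finish reading.
24	cognitive	Planning everyday activities has become noticeably harder for her.
25	cognitive	He has grown forgetful and misplaces household items daily.
26	cognitive	The patient is easily distractible during extended conversations.
27	cognitive	Decision making about routine matters now takes considerable effort.
28	cognitive	Episodes of confusion were noted by family members this month.
29	cognitive	Attention lapses occur frequently when driving or cooking.
30	cognitive	Memory problems have affected her performance at work.
31	arousal_regulatory	Patient reports poor sleep with frequent awakenings overnight.
32	arousal_regulatory	Chronic insomnia persists despite good sleep hygiene practices.
33	arousal_regulatory	He describes persistent hyperarousal and feeling constantly on edge.
34	arousal_regulatory	An exaggerated startle response was observed during the examination.
35	arousal_regulatory	Vivid nightmares wake him several times each week.
36	arousal_regulatory	She reports ongoing nervousness and difficulty relaxing at home.
37	arousal_regulatory	Patient feels restless and unable to sit still in the evenings.
38	arousal_regulatory	Daytime fatigue follows nights of fragmented sleep.
39	arousal_regulatory	Physiological stress reactions include sweating and a racing heart.
40	arousal_regulatory	Sleep onset is delayed by two hours on most nights.
41	social_processes	Patient expresses profound shame about events during the deployment.
42	social_processes	Persistent guilt over the incident dominates her thinking.
43	social_processes	Insecure attachment patterns complicate his close relationships.
44	social_processes	She describes increasing isolation from friends and relatives.
45	social_processes	Marked social withdrawal has been noted since the hospitalization.
46	social_processes	Deep distrust of others prevents him from seeking support.
47	social_processes	Episodes of verbal aggression have strained the marriage.
48	social_processes	He voices paranoid concerns that coworkers are talking about him.
49	social_processes	Feelings of shame keep the patient from attending group sessions.
50	social_processes	Guilt about surviving the crash remains a central theme.
51	sensorimotor	A fine resting tremor was noted in both hands.
52	sensorimotor	Her gait is slow and unsteady on level ground.
53	sensorimotor	Impaired coordination makes buttoning clothing difficult for him.
54	sensorimotor	Psychomotor slowing was evident throughout the assessment.
55	sensorimotor	Patient reports poor balance and two recent falls at home.
56	sensorimotor	Persistent muscle tension in the neck and shoulders is reported.
57	sensorimotor	Slowed movements were observed when the patient rose from the chair.
58	sensorimotor	Increasing clumsiness has led to dropped objects at work.
59	sensorimotor	Tremor worsens when the patient is fatigued or stressed.
60	sensorimotor	Balance problems limit her ability to use stairs safely.
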