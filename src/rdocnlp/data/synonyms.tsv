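word	synonym
patient	client
reports	describes
describes	reports
endorses	reports
intense	severe
frequent	recurrent
constant	continual
ongoing	persistent
persistent	continuing
marked	pronounced
significant	notable
daily	everyday
difficulty	trouble
worsening	deteriorating
noted	observed
observed	seen
several	multiple
remains	stays
little	minimal
poor	diminished
evident	apparent
profound	deep
increasing	growing
limit	restrict
strained	burdened
struggling	wrestling
unable	incapable
evenings	nights
week	wk
month	mo
family	relatives
home	house
work	workplace
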