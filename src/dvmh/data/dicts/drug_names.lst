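# Prescribed medications used to treat mental health disorders.
# surface <TAB> canonical <TAB> medication_class=...
zoloft	Zoloft	medication_class=antidepressant
prozac	Prozac	medication_class=antidepressant
lexapro	Lexapro	medication_class=antidepressant
escitalopram	Escitalopram	medication_class=antidepressant
citalopram	Citalopram	medication_class=antidepressant
anafranil	Anafranil	medication_class=antidepressant
effexor	Effexor	medication_class=antidepressant
cymbalta	Cymbalta	medication_class=antidepressant
paxil	Paxil	medication_class=antidepressant
aropax	Aropax	medication_class=antidepressant
celexa	Celexa	medication_class=antidepressant
luvox	Luvox	medication_class=antidepressant
sertraline	Sertraline	medication_class=antidepressant
fluoxetine	Fluoxetine	medication_class=antidepressant
mirtazapine	Mirtazapine	medication_class=antidepressant
avanza	Avanza	medication_class=antidepressant
endep	Endep	medication_class=antidepressant
valdoxan	Valdoxan	medication_class=antidepressant
xanax	Xanax	medication_class=antianxiety
valium	Valium	medication_class=antianxiety
tensium	Tensium	medication_class=antianxiety
alprazolam	Alprazolam	medication_class=antianxiety
diazepam	Diazepam	medication_class=antianxiety
temazepam	Temazepam	medication_class=antianxiety
ativan	Ativan	medication_class=antianxiety
lorazepam	Lorazepam	medication_class=antianxiety
serepax	Serepax	medication_class=antianxiety
klonopin	Klonopin	medication_class=antianxiety
clonazepam	Clonazepam	medication_class=antianxiety
risperdal	Risperdal	medication_class=antipsychotic
risperidone	Risperidone	medication_class=antipsychotic
clozapine	Clozapine	medication_class=antipsychotic
clozaril	Clozaril	medication_class=antipsychotic
stelazine	Stelazine	medication_class=antipsychotic
seroquel	Seroquel	medication_class=antipsychotic
quetiapine	Quetiapine	medication_class=antipsychotic
zyprexa	Zyprexa	medication_class=antipsychotic
olanzapine	Olanzapine	medication_class=antipsychotic
abilify	Abilify	medication_class=antipsychotic
haldol	Haldol	medication_class=antipsychotic
haloperidol	Haloperidol	medication_class=antipsychotic
largactil	Largactil	medication_class=antipsychotic
lithium	Lithium	medication_class=antipsychotic
modecate	Modecate	medication_class=neuroleptic
fluphenazine	Fluphenazine	medication_class=neuroleptic
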