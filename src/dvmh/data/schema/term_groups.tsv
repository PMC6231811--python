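term	category
depression	Major depressive disorder, single episode
postpartum depression	Postpartum depression
anxiety	Other anxiety disorders
anxiety disorder	Anxiety disorder, unspecified
generalized anxiety disorder	Generalized anxiety disorder
panic disorder	Panic disorder
phobia	Phobic anxiety disorders
posttraumatic stress disorder	Posttraumatic stress disorder
obsessive-compulsive disorder	Obsessive-compulsive disorder, unspecified
adjustment disorder	Reaction to severe stress, and adjustment disorders
schizophrenia	Schizophrenia, unspecified
paranoid schizophrenia	Paranoid schizophrenia
schizoaffective disorder	Schizoaffective disorders
schizotypal disorder	Schizotypal disorder
psychosis	Unspecified psychosis not due to a substance or known physiological condition
delusional disorder	Delusional disorders
paranoia	Delusional disorders
bipolar disorder	Bipolar disorder, unspecified
mania	Manic episode
mood disorder	Mood (affective) disorders
cyclothymic disorder	Cyclothymic disorder
dysthymia	Dysthymia
alcohol abuse	Alcohol abuse
substance abuse	Substance abuse (unspecified)
drug-induced disorder	Unspecified drug-induced disorders
prescription drug abuse	Drug prescription abuse
cannabis abuse	Cannabis abuse
opioid abuse	Opioid related disorders
stimulant abuse	Other stimulant related disorders
cocaine abuse	Cocaine related disorders
other psychoactive substance abuse	Other psychoactive substance related disorders
nicotine dependence	Other psychoactive substance related disorders
attention deficit hyperactivity disorder	Attention deficit hyperactivity disorder
conduct disorder	Conduct disorder, unspecified
oppositional defiance disorder	Oppositional defiance disorder
transient tic disorder	Transient tic disorder
autism	Autism
asperger syndrome	Asperger syndrome
intellectual disability	Intellectual disability, unspecified
severe intellectual disability	Intellectual disability, severe
mild intellectual disability	Intellectual disability, mild
down syndrome	Down syndrome, unspecified
dementia	Dementia, unspecified
vascular dementia	Vascular dementia
alzheimer disease	Alzheimer's disease, unspecified
frontotemporal dementia	Frontotemporal dementia
huntington disease	Systemic atrophies primarily affecting the central nervous system
traumatic brain injury	Traumatic brain injury
self-harm	Intentional self-harm
suicide attempt	Suicide attempt
suicidal ideation	Suicidal ideations
suicidal tendencies	Suicidal ideations
anger issues	Symptoms and signs involving emotional state
eating disorder	Eating disorders
anorexia nervosa	Anorexia nervosa
bulimia nervosa	Bulimia nervosa
body dysmorphic disorder	Body dysmorphic disorder
personality disorder	Personality disorder, unspecified
borderline personality disorder	Borderline personality disorder
paranoid personality disorder	Paranoid personality disorder
antisocial personality disorder	Antisocial personality disorder
narcissistic	Narcissistic personality disorder
narcissism	Narcissistic personality disorder
dissociative identity disorder	Dissociative identity disorder
dissociative disorder	Dissociative and conversion disorders
kleptomania	Kleptomania
intermittent explosive disorder	Intermittent explosive disorder
impulse control disorder	Impulse disorders
unspecified mental health disorder	Unspecified mental disorder
neurological disorder	Unspecified diseases of the nervous system
antidepressant medication	Medications-antidepressants
antianxiety medication	Medications-antianxiety
antipsychotic medication	Medications-antipsychotics
neuroleptic medication	Medications-neuroleptics
mood stabilizer medication	Medications-antipsychotics
zoloft	Medications-antidepressants
prozac	Medications-antidepressants
lexapro	Medications-antidepressants
escitalopram	Medications-antidepressants
citalopram	Medications-antidepressants
anafranil	Medications-antidepressants
effexor	Medications-antidepressants
cymbalta	Medications-antidepressants
paxil	Medications-antidepressants
aropax	Medications-antidepressants
celexa	Medications-antidepressants
luvox	Medications-antidepressants
sertraline	Medications-antidepressants
fluoxetine	Medications-antidepressants
mirtazapine	Medications-antidepressants
avanza	Medications-antidepressants
endep	Medications-antidepressants
valdoxan	Medications-antidepressants
xanax	Medications-antianxiety
valium	Medications-antianxiety
tensium	Medications-antianxiety
alprazolam	Medications-antianxiety
diazepam	Medications-antianxiety
temazepam	Medications-antianxiety
ativan	Medications-antianxiety
lorazepam	Medications-antianxiety
serepax	Medications-antianxiety
klonopin	Medications-antianxiety
clonazepam	Medications-antianxiety
risperdal	Medications-antipsychotics
risperidone	Medications-antipsychotics
clozapine	Medications-antipsychotics
clozaril	Medications-antipsychotics
stelazine	Medications-antipsychotics
seroquel	Medications-antipsychotics
quetiapine	Medications-antipsychotics
zyprexa	Medications-antipsychotics
olanzapine	Medications-antipsychotics
abilify	Medications-antipsychotics
haldol	Medications-antipsychotics
haloperidol	Medications-antipsychotics
largactil	Medications-antipsychotics
lithium	Medications-antipsychotics
modecate	Medications-neuroleptics
fluphenazine	Medications-neuroleptics
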