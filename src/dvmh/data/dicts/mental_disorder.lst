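# Mental-health disorder terms: ICD-derived names, unofficial phrases,
# abbreviations and observed misspellings. Columns: surface <TAB> canonical.
depression	Depression
depresion	Depression	misspelling=1
depressionn	Depression	misspelling=1
depressive disorder	Depression
major depression	Depression
clinical depression	Depression
postnatal depression	Postpartum depression
post-natal depression	Postpartum depression
postpartum depression	Postpartum depression
anxiety	Anxiety
anxeity	Anxiety	misspelling=1
anxietty	Anxiety	misspelling=1
anxiety disorder	Anxiety
generalized anxiety disorder	Generalized anxiety disorder
generalised anxiety disorder	Generalized anxiety disorder
panic disorder	Panic disorder
panic attacks	Panic disorder
phobia	Phobia
ptsd	Posttraumatic stress disorder
posttraumatic stress disorder	Posttraumatic stress disorder
post-traumatic stress disorder	Posttraumatic stress disorder
post traumatic stress disorder	Posttraumatic stress disorder
ocd	Obsessive-compulsive disorder
obsessive compulsive disorder	Obsessive-compulsive disorder
obsessive-compulsive disorder	Obsessive-compulsive disorder
adjustment disorder	Adjustment disorder
schizophrenia	Schizophrenia
schitzophrenia	Schizophrenia	misspelling=1
scitzophrenia	Schizophrenia	misspelling=1
shizophrenia	Schizophrenia	misspelling=1
paranoid schizophrenia	Paranoid schizophrenia
schizoaffective disorder	Schizoaffective disorder
schizotypal disorder	Schizotypal disorder
psychosis	Psychosis
psychotic episode	Psychosis
psychotic episodes	Psychosis
delusions	Delusional disorder
delusional disorder	Delusional disorder
paranoia	Paranoia
bipolar disorder	Bipolar disorder
bipolar	Bipolar disorder
bi-polar	Bipolar disorder
bipola	Bipolar disorder	misspelling=1
manic depression	Bipolar disorder
mania	Mania
manic episode	Mania
manic episodes	Mania
mood disorder	Mood disorder
cyclothymia	Cyclothymic disorder
cyclothymic disorder	Cyclothymic disorder
dysthymia	Dysthymia
alcoholism	Alcohol abuse
alcohol abuse	Alcohol abuse
alcohol addiction	Alcohol abuse
alcohol dependence	Alcohol abuse
alcohol problem	Alcohol abuse
abuses alcohol	Alcohol abuse
drinking problem	Alcohol abuse
substance abuse	Substance abuse
substance abuse problem	Substance abuse
drug abuse	Substance abuse
drug problem	Substance abuse
ongoing drug abuse problems	Substance abuse
drug-induced psychosis	Drug-induced disorder
drug induced psychosis	Drug-induced disorder
drug-induced disorder	Drug-induced disorder
abusing prescribed medication	Prescription drug abuse
abuses prescribed medication	Prescription drug abuse
prescription drug abuse	Prescription drug abuse
cannabis addiction	Cannabis abuse
cannabis abuse	Cannabis abuse
nicotine dependence	Nicotine dependence
adhd	Attention deficit hyperactivity disorder
attention deficit hyperactivity disorder	Attention deficit hyperactivity disorder
attention deficit disorder	Attention deficit hyperactivity disorder
conduct disorder	Conduct disorder
oppositional defiant disorder	Oppositional defiance disorder
oppositional defiance disorder	Oppositional defiance disorder
transient tic disorder	Transient tic disorder
autism	Autism
autism spectrum disorder	Autism
aspergers	Asperger syndrome
asperger syndrome	Asperger syndrome
asperger's syndrome	Asperger syndrome
aspergus syndrome	Asperger syndrome	misspelling=1
intellectual disability	Intellectual disability
severe intellectual disability	Severe intellectual disability
mild intellectual disability	Mild intellectual disability
down syndrome	Down syndrome
down's syndrome	Down syndrome
dementia	Dementia
vascular dementia	Vascular dementia
alzheimers	Alzheimer disease
alzheimer's	Alzheimer disease
alzheimer's disease	Alzheimer disease
alzheimers disease	Alzheimer disease
frontotemporal dementia	Frontotemporal dementia
huntington disease	Huntington disease
huntington's disease	Huntington disease
brain damage	Traumatic brain injury
brain injury	Traumatic brain injury
brain trauma	Traumatic brain injury
serious brain injury	Traumatic brain injury
acquired brain injury	Traumatic brain injury
traumatic brain injury	Traumatic brain injury
self-harm	Self-harm
self harm	Self-harm
selfharm	Self-harm
self-harming	Self-harm
self-harming issues	Self-harm
self-harms	Self-harm
cut herself	Self-harm
cut himself	Self-harm
cuts herself	Self-harm
cuts himself	Self-harm
cutting herself	Self-harm
cutting himself	Self-harm
suicide attempt	Suicide attempt
suicide attempts	Suicide attempt
attempted suicide	Suicide attempt
multiple suicide attempts	Suicide attempt
attempted to kill himself	Suicide attempt
attempted to kill herself	Suicide attempt
tried to kill himself	Suicide attempt
tried to kill herself	Suicide attempt
suicidal ideation	Suicidal ideation
suicidal ideations	Suicidal ideation
suicidal thoughts	Suicidal ideation
suicidal tendencies	Suicidal tendencies
anger issues	Anger issues
anger management issues	Anger issues
eating disorder	Eating disorder
anorexia	Anorexia nervosa
anorexia nervosa	Anorexia nervosa
bulimia	Bulimia nervosa
bulimia nervosa	Bulimia nervosa
body dysmorphic disorder	Body dysmorphic disorder
personality disorder	Personality disorder
borderline personality disorder	Borderline personality disorder
bpd	Borderline personality disorder
paranoid personality disorder	Paranoid personality disorder
antisocial personality disorder	Antisocial personality disorder
narcissism	Narcissistic
narcissistic personality disorder	Narcissistic
split personality	Dissociative identity disorder
split personality disorder	Dissociative identity disorder
multiple personality disorder	Dissociative identity disorder
dissociative identity disorder	Dissociative identity disorder
dissociative disorder	Dissociative disorder
kleptomania	Kleptomania
intermittent explosive disorder	Intermittent explosive disorder
impulse control disorder	Impulse control disorder
mental health issues	Unspecified mental health disorder
mental health issue	Unspecified mental health disorder
mental health problems	Unspecified mental health disorder
mental health problem	Unspecified mental health disorder
mental health condition	Unspecified mental health disorder
mental health disorder	Unspecified mental health disorder
mental condition	Unspecified mental health disorder
mental illness	Unspecified mental health disorder
mental disorder	Unspecified mental health disorder
severe mental disorder	Unspecified mental health disorder
psychiatric condition	Unspecified mental health disorder
psychiatric issues	Unspecified mental health disorder
neurological disorder	Neurological disorder
neurological condition	Neurological disorder
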