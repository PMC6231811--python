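# Adjectives indicating a mental disorder (copula patterns: "POI is schizophrenic").
alcoholic	Alcohol abuse
schizophrenic	Schizophrenia
skitzophrenic	Schizophrenia	misspelling=1
bipolar	Bipolar disorder
bi-polar	Bipolar disorder
autistic	Autism
depressed	Depression
depressive	Depression
anxious	Anxiety
suicidal	Suicidal ideation
psychotic	Psychosis
delusional	Delusional disorder
paranoid	Paranoia
manic	Mania
demented	Dementia
anorexic	Anorexia nervosa
bulimic	Bulimia nervosa
narcissistic	Narcissistic
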