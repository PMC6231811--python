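level	name	parent
1	Mental disorders due to known physiological conditions
1	Mental and behavioral disorders due to psychoactive substance use
1	Schizophrenia, schizotypal, delusional, and other non-mood psychotic disorders
1	Mood (affective) disorders
1	Anxiety, dissociative, stress-related, somatoform, and other nonpsychotic mental disorders
1	Behavioral syndromes associated with physiological disturbances and physical factors
1	Disorders of adult personality and behavior
1	Intellectual disabilities
1	Pervasive and specific developmental disorders
1	Behavioral and emotional disorders with onset usually occurring in childhood and adolescence
1	Unspecified mental disorder
1	Intentional self-harm
1	Injury of unspecified body region
1	Symptoms, signs, and abnormal clinical and laboratory findings
1	Other degenerate diseases of the nervous system
1	Chromosomal abnormalities, not elsewhere classified
1	Drug prescription abuse
1	Traumatic brain injury
1	Substance abuse (unspecified)
1	Medications-antipsychotics
1	Medications-neuroleptics
1	Medications-antianxiety
1	Medications-antidepressants
1	Unspecified drug-induced disorders
1	Unspecified diseases of the nervous system
1	Systemic atrophies primarily affecting the central nervous system
2	Dementia, unspecified	Mental disorders due to known physiological conditions
2	Vascular dementia	Mental disorders due to known physiological conditions
2	Alcohol abuse	Mental and behavioral disorders due to psychoactive substance use
2	Cannabis abuse	Mental and behavioral disorders due to psychoactive substance use
2	Opioid related disorders	Mental and behavioral disorders due to psychoactive substance use
2	Cocaine related disorders	Mental and behavioral disorders due to psychoactive substance use
2	Other stimulant related disorders	Mental and behavioral disorders due to psychoactive substance use
2	Other psychoactive substance related disorders	Mental and behavioral disorders due to psychoactive substance use
2	Schizophrenia	Schizophrenia, schizotypal, delusional, and other non-mood psychotic disorders
2	Schizotypal disorder	Schizophrenia, schizotypal, delusional, and other non-mood psychotic disorders
2	Delusional disorders	Schizophrenia, schizotypal, delusional, and other non-mood psychotic disorders
2	Schizoaffective disorders	Schizophrenia, schizotypal, delusional, and other non-mood psychotic disorders
2	Unspecified psychosis not due to a substance or known physiological condition	Schizophrenia, schizotypal, delusional, and other non-mood psychotic disorders
2	Major depressive disorder, single episode	Mood (affective) disorders
2	Bipolar disorder	Mood (affective) disorders
2	Manic episode	Mood (affective) disorders
2	Persistent mood disorder	Mood (affective) disorders
2	Other anxiety disorders	Anxiety, dissociative, stress-related, somatoform, and other nonpsychotic mental disorders
2	Phobic anxiety disorders	Anxiety, dissociative, stress-related, somatoform, and other nonpsychotic mental disorders
2	Reaction to severe stress, and adjustment disorders	Anxiety, dissociative, stress-related, somatoform, and other nonpsychotic mental disorders
2	Obsessive-compulsive disorder	Anxiety, dissociative, stress-related, somatoform, and other nonpsychotic mental disorders
2	Dissociative and conversion disorders	Anxiety, dissociative, stress-related, somatoform, and other nonpsychotic mental disorders
2	Somatoform disorders	Anxiety, dissociative, stress-related, somatoform, and other nonpsychotic mental disorders
2	Eating disorders	Behavioral syndromes associated with physiological disturbances and physical factors
2	Specific personality disorders	Disorders of adult personality and behavior
2	Impulse disorders	Disorders of adult personality and behavior
2	Intellectual disability, unspecified	Intellectual disabilities
2	Intellectual disability, mild	Intellectual disabilities
2	Intellectual disability, severe	Intellectual disabilities
2	Pervasive developmental disorder	Pervasive and specific developmental disorders
2	Attention deficit hyperactivity disorder	Behavioral and emotional disorders with onset usually occurring in childhood and adolescence
2	Conduct disorders	Behavioral and emotional disorders with onset usually occurring in childhood and adolescence
2	Tic disorders	Behavioral and emotional disorders with onset usually occurring in childhood and adolescence
2	Other behavioral and emotional disorders with onset usually occurring in childhood and adolescence	Behavioral and emotional disorders with onset usually occurring in childhood and adolescence
2	Injury of unspecified body region	Injury of unspecified body region
2	Symptoms and signs involving emotional state	Symptoms, signs, and abnormal clinical and laboratory findings
2	Alzheimer disease	Other degenerate diseases of the nervous system
2	Frontotemporal dementia	Other degenerate diseases of the nervous system
2	Down syndrome	Chromosomal abnormalities, not elsewhere classified
3	Schizophrenia, unspecified	Schizophrenia
3	Paranoid schizophrenia	Schizophrenia
3	Bipolar disorder, unspecified	Bipolar disorder
3	Postpartum depression	Major depressive disorder, single episode
3	Cyclothymic disorder	Persistent mood disorder
3	Dysthymia	Persistent mood disorder
3	Anxiety disorder, unspecified	Other anxiety disorders
3	Generalized anxiety disorder	Other anxiety disorders
3	Panic disorder	Other anxiety disorders
3	Posttraumatic stress disorder	Reaction to severe stress, and adjustment disorders
3	Obsessive-compulsive disorder, unspecified	Obsessive-compulsive disorder
3	Dissociative identity disorder	Dissociative and conversion disorders
3	Body dysmorphic disorder	Somatoform disorders
3	Anorexia nervosa	Eating disorders
3	Bulimia nervosa	Eating disorders
3	Personality disorder, unspecified	Specific personality disorders
3	Borderline personality disorder	Specific personality disorders
3	Paranoid personality disorder	Specific personality disorders
3	Narcissistic personality disorder	Specific personality disorders
3	Antisocial personality disorder	Specific personality disorders
3	Kleptomania	Impulse disorders
3	Other impulse disorders	Impulse disorders
3	Autism	Pervasive developmental disorder
3	Asperger syndrome	Pervasive developmental disorder
3	Oppositional defiance disorder	Conduct disorders
3	Conduct disorder, unspecified	Conduct disorders
3	Transient tic disorder	Tic disorders
3	Unspecified behavioral and emotional disorders with onset usually occurring in childhood and adolescence	Other behavioral and emotional disorders with onset usually occurring in childhood and adolescence
3	Suicide attempt	Injury of unspecified body region
3	Suicidal ideations	Symptoms and signs involving emotional state
3	Alzheimer's disease, unspecified	Alzheimer disease
3	Down syndrome, unspecified	Down syndrome
4	Intermittent explosive disorder	Other impulse disorders
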