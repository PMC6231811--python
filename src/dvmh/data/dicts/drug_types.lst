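# Medication classes used in treating mental health disorders.
antidepressant	Antidepressant medication
antidepressants	Antidepressant medication
anti-depressants	Antidepressant medication
antidepressant medication	Antidepressant medication
antidepressant medications	Antidepressant medication
antianxiety	Antianxiety medication
antianxiety medication	Antianxiety medication
antianxiety medications	Antianxiety medication
anti-anxiety medication	Antianxiety medication
anxiolytics	Antianxiety medication
benzodiazepines	Antianxiety medication
benzos	Antianxiety medication
antipsychotic	Antipsychotic medication
antipsychotics	Antipsychotic medication
anti-psychotics	Antipsychotic medication
antipsychotic medication	Antipsychotic medication
antipsychotic medications	Antipsychotic medication
neuroleptic	Neuroleptic medication
neuroleptics	Neuroleptic medication
neuroleptic medication	Neuroleptic medication
neuroleptic medications	Neuroleptic medication
neuroleptic drugs	Neuroleptic medication
mood stabilizer	Mood stabilizer medication
mood stabilizers	Mood stabilizer medication
mood stabiliser	Mood stabilizer medication
mood stabilisers	Mood stabilizer medication
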