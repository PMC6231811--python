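# Role-attributed disorder-mention rules (composed; see docs/methods.md)

rule poi_verb_mental_disorder
role POI
pattern dict:poi dict:have? dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:mental_disorder

rule poi_verb_drug_names
role POI
pattern dict:poi dict:have? dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:drug_names

rule poi_verb_drug_types
role POI
pattern dict:poi dict:have? dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:drug_types

rule poi_verb_drug_addiction
role POI
pattern dict:poi dict:have? dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:drug_addiction

rule poi_hist_mental_disorder
role POI
pattern dict:poi not:negation{0,1} dict:have? not:negation{0,1} dict:history cap:mental_disorder

rule poi_hist_drug_addiction
role POI
pattern dict:poi not:negation{0,1} dict:have? not:negation{0,1} dict:history cap:drug_addiction

rule poi_have_mental_disorder
role POI
pattern dict:poi not:negation{0,1} dict:have not:negation{0,2} cap:mental_disorder

rule poi_cop_adjectives
role POI
pattern dict:poi dict:be not:negation{0,1} cap:adjectives

rule poi_direct_mental_disorder
role POI
pattern dict:poi not:negation{0,3} cap:mental_disorder

rule victim_verb_mental_disorder
role victim
pattern dict:victim dict:have? dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:mental_disorder

rule victim_verb_drug_names
role victim
pattern dict:victim dict:have? dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:drug_names

rule victim_verb_drug_types
role victim
pattern dict:victim dict:have? dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:drug_types

rule victim_verb_drug_addiction
role victim
pattern dict:victim dict:have? dict:be? not:negation{0,1} dict:verbs not:negation{0,3} cap:drug_addiction

rule victim_hist_mental_disorder
role victim
pattern dict:victim not:negation{0,1} dict:have? not:negation{0,1} dict:history cap:mental_disorder

rule victim_hist_drug_addiction
role victim
pattern dict:victim not:negation{0,1} dict:have? not:negation{0,1} dict:history cap:drug_addiction

rule victim_have_mental_disorder
role victim
pattern dict:victim not:negation{0,1} dict:have not:negation{0,2} cap:mental_disorder

rule victim_cop_adjectives
role victim
pattern dict:victim dict:be not:negation{0,1} cap:adjectives

rule victim_direct_mental_disorder
role victim
pattern dict:victim not:negation{0,3} cap:mental_disorder
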