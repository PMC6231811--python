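# Terms describing a person of interest (POI) in a DV event.
poi
pois
poi accused
accused
defendant
defendants
offender
offenders
suspect
perpetrator
assailant
person of interest
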