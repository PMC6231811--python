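# Terms indicating a family relationship.
mother
father
brother
sister
son
daughter
cousin
grandfather
grandmother
uncle
aunt
stepfather
stepmother
nephew
niece
husband
wife
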