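# Embryo-level counts of the clinical cohort that are not derivable from
# the per-family cycle table.
inconclusive_embryos	37
aneuploid_embryos	130
malbac_failures	3
ado_events	14
pcr_rounds	501
wildtype_transferable	40
carrier_transferable	67
ar_couples	44
couples_without_wildtype	18
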