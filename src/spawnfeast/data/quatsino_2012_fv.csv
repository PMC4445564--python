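# Published annual percent-faecal-volume summary for black bear scats,
# Quatsino Sound 2012 (n = 47 scats, 11 sites).  Items reported only as
# trace (<0.5%) carry 0 here; excluded (non-energetic) items are omitted.
item,fv_pct
brown_algae,38.6
green_algae,0.0
red_algae,0.6
amphipods,5.4
herring_eggs,1.1
seagrasses,39.5
graminoids,5.9
forbs,1.1
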