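# Diet-item definitions for black bear scat analysis on herring-spawn beaches.
#
# cf1 converts percent faecal volume to percent of original diet (dry mass);
# values come from captive brown-bear feeding trials, with substitutions for
# items lacking trials: herring eggs take the whole-trout factor (40.8) and
# macroalgae/seagrasses take the graminoid factor (0.24).
# cf2 is energy density (kJ/g dry weight).  Ants carry their own cf2 (17.7)
# distinct from other arthropods (11.3); talitrid amphipods use a measured
# 10.8.  Items judged to contribute negligible energy (shell fragments, hair,
# woody debris, gravel, garbage...) are excluded from EDC/EDEC entirely.
brown_algae: {group: macroalgae, cf1: 0.24, cf2: 13.14, included: true}
green_algae: {group: macroalgae, cf1: 0.24, cf2: 13.14, included: true}
red_algae: {group: macroalgae, cf1: 0.24, cf2: 13.14, included: true}
seagrasses: {group: land_plants, cf1: 0.24, cf2: 16.8, included: true}
graminoids: {group: land_plants, cf1: 0.24, cf2: 6.3, included: true}
forbs: {group: land_plants, cf1: 0.26, cf2: 8.4, included: true}
herring_eggs: {group: animals, cf1: 40.8, cf2: 18.7, included: true}
amphipods: {group: arthropods, cf1: 1.1, cf2: 10.8, included: true}
ants: {group: arthropods, cf1: 1.1, cf2: 17.7, included: true}
beetles: {group: arthropods, cf1: 1.1, cf2: 11.3, included: true}
flies: {group: arthropods, cf1: 1.1, cf2: 11.3, included: true}
crabs: {group: arthropods, cf1: 1.1, cf2: 11.3, included: true}
barnacles: {group: arthropods, cf1: 1.1, cf2: 11.3, included: true}
molluscs: {group: molluscs, included: false}
bryozoa: {group: bryozoa, included: false}
bear_hair: {group: animals, included: false}
feathers: {group: animals, included: false}
trees_shrubs: {group: land_plants, included: false}
bryophyta: {group: land_plants, included: false}
gravel: {group: inorganic, included: false}
garbage: {group: inorganic, included: false}
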