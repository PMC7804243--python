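{
 "version": 1,
 "comment": "Candidate C10H15O8 peroxy radicals from limonene ozonolysis, routes A and B. Feature flags encode the drawn isomer structures: site class of the peroxy radical carbon, quaternary character of the carbon adjacent to the alkyl radical formed after O2 loss, and functional groups inherited from the aldehydic H-shift (peroxy acid) and earlier autoxidation steps (hydroperoxide). HO2 loss is not part of the observed O8 fragmentation, consistent with a quaternary carbon next to the RO2 site in these isomers.",
 "structures": [
  {"id": "A1", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "1,4 aldehydic-then-saturated H-shift product; all observed O8 losses feasible"},
  {"id": "A2", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "1,6 H-shift product; reference structure for the O8 fragmentation cascade"},
  {"id": "A3", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "tertiary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "tertiary alkylperoxy radical; OH elimination with ketone formation unavailable"},
  {"id": "A4", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": true, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "quaternary carbon adjacent to the post-O2-loss alkyl radical; combined HNO3+OH loss blocked"},
  {"id": "A5", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": true, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "as A4"},
  {"id": "A6", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": true, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "as A4"},
  {"id": "A7", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "1,7 H-shift product; all observed O8 losses feasible"},
  {"id": "B1", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 1, "notes": "route-B analogue of A1; one OOH/OO* H-scrambling site"},
  {"id": "B2", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 1, "notes": "route-B analogue of A2; one OOH/OO* H-scrambling site"},
  {"id": "B3", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "tertiary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 1, "notes": "tertiary alkylperoxy radical; OH elimination unavailable; scrambling relocates the radical to a secondary site", "scramble_variants": [{"ro2_site_class": "secondary"}]},
  {"id": "B4", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": true, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "quaternary alpha carbon; combined HNO3+OH loss blocked"},
  {"id": "B5", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": true, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "as B4"},
  {"id": "B6", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": true, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 0, "notes": "as B4"},
  {"id": "B7", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": true, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "scramble_sites": 1, "notes": "quaternary alpha carbon; H-scrambling relocates the labile H, giving a variant equivalent to A7", "scramble_variants": [{"alpha_carbon_quaternary": false}]}
 ]
}
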