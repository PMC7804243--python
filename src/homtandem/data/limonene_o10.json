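{
 "version": 1,
 "comment": "Candidate C10H15O10 peroxy radicals from limonene, derived from the plausible O8 structures by one further H-shift + O2 addition. Derivative ids follow the parent: e.g. A2-1 is the first O10 derivative of A2. Six candidates are tertiary alkylperoxy radicals (OH elimination blocked); the non-tertiary candidates expose a hydrogen on the carbon next to the RO2 site (HO2 elimination open); A1-2/B1-2 place the post-O2-loss radical away from any peroxy group, blocking CHO3 recombination.",
 "structures": [
  {"id": "A1-1", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": false, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2},
  {"id": "A1-2", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": false, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": false, "scramble_sites": 2, "notes": "radical remote from the peroxy groups; CHO3 recombination blocked"},
  {"id": "A1-6", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "tertiary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2, "notes": "tertiary alkylperoxy radical; OH elimination blocked"},
  {"id": "A2-1", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": false, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2, "notes": "1,5/1,6 H-shift from a saturated carbon; all observed O10 losses feasible"},
  {"id": "A2-5", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "tertiary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2, "notes": "tertiary; OH elimination blocked"},
  {"id": "A7-1", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "tertiary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2, "notes": "tertiary; OH elimination blocked"},
  {"id": "A7-2", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": false, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2, "notes": "all observed O10 losses feasible"},
  {"id": "A7-5", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "tertiary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2, "notes": "tertiary; OH elimination blocked"},
  {"id": "B1-1", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": false, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2},
  {"id": "B1-2", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": false, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": false, "scramble_sites": 2, "notes": "radical remote from the peroxy groups; CHO3 recombination blocked"},
  {"id": "B1-6", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "tertiary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2, "notes": "tertiary; OH elimination blocked"},
  {"id": "B2-1", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "secondary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": false, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2, "notes": "reference structure for the O10 fragmentation cascade"},
  {"id": "B2-6", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "tertiary", "alpha_carbon_quaternary": false, "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "scramble_sites": 2, "notes": "tertiary; OH elimination blocked"}
 ]
}
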