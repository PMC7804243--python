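{
 "version": 1,
 "comment": "Alpha-pinene RO2 pool and the O12 accretion dimer. The bicyclic skeleton carries a gem-dimethyl quaternary carbon, opening the CH3O2 and C3H6O loss channels specific to alpha-pinene peroxy radicals; the O4 radical is an important dimer precursor here.",
 "structures": [
  {"id": "ap-O4", "species": "RO2_radical", "formula": "C10H15O4*", "system": "alpha-pinene", "ro2_site_class": "secondary", "ro2_neighbor_quaternary": true, "has_carbonyl": true, "gem_dimethyl_quaternary": true, "notes": "first-generation peroxy radical; key dimer precursor"},
  {"id": "ap-O6-acyl", "species": "RO2_radical", "formula": "C10H15O6*", "system": "alpha-pinene", "ro2_site_class": "acylperoxy", "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_carbonyl": true, "gem_dimethyl_quaternary": true},
  {"id": "ap-O8", "species": "RO2_radical", "formula": "C10H15O8*", "system": "alpha-pinene", "ro2_site_class": "tertiary", "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "gem_dimethyl_quaternary": true, "notes": "shows O2/CO2 losses plus the alpha-pinene-specific CH3O2 and C3H6O losses"},
  {"id": "ap-O10", "species": "RO2_radical", "formula": "C10H15O10*", "system": "alpha-pinene", "ro2_site_class": "secondary", "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "gem_dimethyl_quaternary": true},
  {"id": "ap-dimer-O12", "species": "dimer", "formula": "C20H30O12", "system": "alpha-pinene", "members": ["ap-O4", "ap-O10"], "notes": "O4 + O10 accretion product"}
 ]
}
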