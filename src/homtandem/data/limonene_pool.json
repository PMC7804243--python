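{
 "version": 1,
 "comment": "Limonene RO2 pool (one representative per oxygen level), the C10H16O8 termination product, and the two dominant ROOR accretion dimers with their member radicals. The O6 radical is acylperoxy (peroxy acid radical from the aldehydic H-shift), which makes one RO-OR cleavage pathway of the O12 dimer unavailable.",
 "structures": [
  {"id": "lim-O4", "species": "RO2_radical", "formula": "C10H15O4*", "system": "limonene", "ro2_site_class": "secondary", "ro2_neighbor_quaternary": true, "has_carbonyl": true, "notes": "first-generation ring-opened peroxy radical"},
  {"id": "lim-O6-acyl", "species": "RO2_radical", "formula": "C10H15O6*", "system": "limonene", "ro2_site_class": "acylperoxy", "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_carbonyl": true, "notes": "acylperoxy radical from the aldehydic H-shift; cannot donate H during RO-OR cleavage"},
  {"id": "lim-O8", "species": "RO2_radical", "formula": "C10H15O8*", "system": "limonene", "ro2_site_class": "secondary", "ro2_neighbor_quaternary": true, "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "notes": "A2-type structure; main dimer precursor"},
  {"id": "lim-O10", "species": "RO2_radical", "formula": "C10H15O10*", "system": "limonene", "ro2_site_class": "secondary", "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "radical_near_peroxy": true, "notes": "A2-1-type structure"},
  {"id": "lim-C10H16O8", "species": "closed_shell", "formula": "C10H16O8", "system": "limonene", "has_hydroperoxide": true, "has_peroxy_acid": true, "has_carbonyl": true, "notes": "termination product of the O8 radical"},
  {"id": "lim-dimer-O12", "species": "dimer", "formula": "C20H30O12", "system": "limonene", "members": ["lim-O6-acyl", "lim-O8"], "notes": "acylperoxy + peroxy accretion product; single cleavage pathway"},
  {"id": "lim-dimer-O14", "species": "dimer", "formula": "C20H30O14", "system": "limonene", "members": ["lim-O8", "lim-O8"], "notes": "symmetric O8 + O8 accretion product; both cleavage pathways open"}
 ]
}
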