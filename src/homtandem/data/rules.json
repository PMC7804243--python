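{
 "version": 1,
 "rules": [
  {
   "id": "R-O2",
   "losses": ["O2"],
   "applies_to": ["RO2_radical"],
   "predicate": "any_peroxy_radical",
   "explanation": "O2 loss removes the peroxy functional group itself and is available to every peroxy radical regardless of site class.",
   "simulated_loss": "O2",
   "dynamic": false
  },
  {
   "id": "R-HNO3",
   "losses": ["HNO3"],
   "applies_to": ["closed_shell", "dimer"],
   "predicate": "always",
   "explanation": "HNO3 loss (declustering with proton transfer) is a common fragmentation of closed-shell nitrate adducts and is rare or insignificant for RO2 radical adducts.",
   "simulated_loss": "HNO3",
   "dynamic": false
  },
  {
   "id": "R-HNO3-OH",
   "losses": ["H2NO4"],
   "applies_to": ["RO2_radical"],
   "predicate": "alpha_not_quaternary",
   "explanation": "Combined HNO3 + OH loss after O2 elimination requires an abstractable hydrogen on the carbon adjacent to the alkyl radical; a quaternary alpha carbon blocks it.",
   "simulated_loss": "H2NO4",
   "dynamic": false
  },
  {
   "id": "R-H2O",
   "losses": ["H2O"],
   "applies_to": ["RO2_radical", "closed_shell"],
   "predicate": "has_hydroperoxide",
   "explanation": "H2O elimination in negative mode proceeds on a hydroperoxide (-OOH) functional group.",
   "simulated_loss": "H2O",
   "dynamic": false
  },
  {
   "id": "R-CO2",
   "losses": ["CO2"],
   "applies_to": ["RO2_radical", "closed_shell"],
   "predicate": "has_acid_group",
   "explanation": "Charge-migration CO2 elimination is indicative of a carboxylic acid moiety, here typically the acid arising from a peroxy acid group.",
   "simulated_loss": "CO2",
   "dynamic": false
  },
  {
   "id": "R-OH",
   "losses": ["HO"],
   "applies_to": ["RO2_radical"],
   "predicate": "not_tertiary",
   "explanation": "OH elimination via intramolecular H-abstraction from the peroxy radical moiety, with ketone formation, is not possible for a tertiary alkylperoxy radical.",
   "simulated_loss": "HO",
   "dynamic": false
  },
  {
   "id": "R-HO2",
   "losses": ["HO2"],
   "applies_to": ["RO2_radical"],
   "predicate": "ro2_neighbor_not_quaternary",
   "explanation": "HO2 elimination (concerted, forming a double bond) occurs only when the carbon next to the RO2 site is not quaternary.",
   "simulated_loss": "HO2",
   "dynamic": false
  },
  {
   "id": "R-CHO3",
   "losses": ["CHO3", "CHO5"],
   "applies_to": ["RO2_radical"],
   "predicate": "radical_near_peroxy",
   "explanation": "CHO3 loss proceeds by recombination of the carbon radical with a nearby peroxy group; from an intact RO2 adduct the observable single-step composition is CHO5 (O2 elimination followed by CHO3).",
   "simulated_loss": "CHO5",
   "dynamic": false
  },
  {
   "id": "R-CH3O2",
   "losses": ["CH3O2"],
   "applies_to": ["RO2_radical"],
   "predicate": "gem_dimethyl",
   "explanation": "CH3O2 loss requires a methyl group on the quaternary gem-dimethyl carbon characteristic of bicyclic (alpha-pinene-type) peroxy radicals.",
   "simulated_loss": "CH3O2",
   "dynamic": false
  },
  {
   "id": "R-C3H6O",
   "losses": ["C3H6O"],
   "applies_to": ["RO2_radical"],
   "predicate": "gem_dimethyl",
   "explanation": "C3H6O loss (acetone-sized fragment) likewise marks the gem-dimethyl quaternary carbon motif.",
   "simulated_loss": "C3H6O",
   "dynamic": false
  },
  {
   "id": "R-ROOR",
   "losses": [],
   "applies_to": ["dimer"],
   "predicate": "always",
   "explanation": "ROOR accretion products cleave at the peroxide RO-OR bond into two alkoxy radicals with in-cage H-exchange, yielding monomer-sized carbonyl (-H) and alcohol (+H) adduct ions; an acylperoxy-derived side cannot donate H, leaving only one pathway.",
   "simulated_loss": null,
   "dynamic": true
  }
 ]
}
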