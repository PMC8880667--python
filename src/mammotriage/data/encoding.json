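{
 "version": "1",
 "description": "Crisp ordinal encodings of the categorical mammography/history descriptors, ordered by suspicion on each variable's universe. Shipped as data so clinical teams can re-map categories.",
 "fields": {
  "mass_shape": {
   "none": 0,
   "oval": 2,
   "round": 4,
   "irregular": 8
  },
  "mass_margins": {
   "none": 0,
   "circumscribed": 1,
   "obscured": 3,
   "microlobulated": 5,
   "indistinct": 7,
   "spiculated": 9
  },
  "mass_density": {
   "none": 0,
   "fat-containing": 1,
   "low": 3,
   "equal": 5,
   "high": 8
  },
  "calc_primacy": {
   "none": 0,
   "associated": 4,
   "primary": 7
  },
  "calc_shape": {
   "none": 0,
   "typically-benign": 1,
   "amorphous": 4,
   "coarse-heterogeneous": 6,
   "fine-pleomorphic": 8,
   "fine-linear-branching": 9
  },
  "calc_distribution": {
   "none": 0,
   "diffuse": 2,
   "regional": 4,
   "grouped": 5,
   "linear": 7,
   "segmental": 8
  },
  "asym_type": {
   "none": 0,
   "global": 3,
   "focal": 6,
   "developing": 8
  },
  "distortion_primacy": {
   "none": 0,
   "associated": 5,
   "primary": 8
  },
  "birads": {
   "0": 0,
   "1": 1,
   "2": 2,
   "3": 3,
   "4A": 4,
   "4B": 5,
   "4C": 6,
   "5": 7,
   "6": 8
  },
  "breast_density": {
   "fatty": 1,
   "scattered": 3,
   "heterogeneously-dense": 6,
   "extremely-dense": 9
  },
  "patient_history": {
   "no": 0,
   "unknown": 5,
   "yes": 10
  },
  "family_history": {
   "none": 0,
   "minor": 4,
   "unknown": 5,
   "major": 9
  }
 }
}
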