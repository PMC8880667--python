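{
 "name": "es1a-masses",
 "version": "1",
 "inputs": [
  {
   "name": "mass_shape",
   "universe": [
    0,
    10
   ],
   "terms": {
    "benign": {
     "kind": "triangular",
     "params": [
      0.0,
      0.0,
      4.0
     ]
    },
    "intermediate": {
     "kind": "triangular",
     "params": [
      2.0,
      5.0,
      8.0
     ]
    },
    "suspicious": {
     "kind": "triangular",
     "params": [
      6.0,
      10.0,
      10.0
     ]
    }
   }
  },
  {
   "name": "mass_margins",
   "universe": [
    0,
    10
   ],
   "terms": {
    "benign": {
     "kind": "triangular",
     "params": [
      0.0,
      0.0,
      4.0
     ]
    },
    "intermediate": {
     "kind": "triangular",
     "params": [
      2.0,
      5.0,
      8.0
     ]
    },
    "suspicious": {
     "kind": "triangular",
     "params": [
      6.0,
      10.0,
      10.0
     ]
    }
   }
  },
  {
   "name": "mass_density",
   "universe": [
    0,
    10
   ],
   "terms": {
    "benign": {
     "kind": "triangular",
     "params": [
      0.0,
      0.0,
      4.0
     ]
    },
    "intermediate": {
     "kind": "triangular",
     "params": [
      2.0,
      5.0,
      8.0
     ]
    },
    "suspicious": {
     "kind": "triangular",
     "params": [
      6.0,
      10.0,
      10.0
     ]
    }
   }
  }
 ],
 "output": {
  "name": "r1a",
  "universe": [
   0,
   100
  ],
  "terms": {
   "low": {
    "kind": "triangular",
    "params": [
     0.0,
     0.0,
     40.0
    ]
   },
   "medium": {
    "kind": "triangular",
    "params": [
     20.0,
     50.0,
     80.0
    ]
   },
   "high": {
    "kind": "triangular",
    "params": [
     60.0,
     100.0,
     100.0
    ]
   }
  }
 },
 "rules": [
  {
   "if": [
    [
     "mass_shape",
     "benign"
    ],
    [
     "mass_margins",
     "benign"
    ]
   ],
   "connective": "AND",
   "then": [
    "r1a",
    "low"
   ]
  },
  {
   "if": [
    [
     "mass_shape",
     "intermediate"
    ],
    [
     "mass_margins",
     "intermediate"
    ]
   ],
   "connective": "OR",
   "then": [
    "r1a",
    "medium"
   ]
  },
  {
   "if": [
    [
     "mass_density",
     "intermediate"
    ]
   ],
   "connective": "AND",
   "then": [
    "r1a",
    "medium"
   ]
  },
  {
   "if": [
    [
     "mass_shape",
     "suspicious"
    ],
    [
     "mass_margins",
     "suspicious"
    ]
   ],
   "connective": "OR",
   "then": [
    "r1a",
    "high"
   ]
  },
  {
   "if": [
    [
     "mass_density",
     "suspicious"
    ]
   ],
   "connective": "AND",
   "then": [
    "r1a",
    "high"
   ]
  }
 ]
}
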