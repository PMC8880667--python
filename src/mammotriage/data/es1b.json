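{
 "name": "es1b-calcifications",
 "version": "1",
 "inputs": [
  {
   "name": "calc_primacy",
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
   "name": "calc_shape",
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
   "name": "calc_distribution",
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
  "name": "r1b",
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
     "calc_primacy",
     "benign"
    ],
    [
     "calc_shape",
     "benign"
    ]
   ],
   "connective": "AND",
   "then": [
    "r1b",
    "low"
   ]
  },
  {
   "if": [
    [
     "calc_shape",
     "intermediate"
    ],
    [
     "calc_distribution",
     "intermediate"
    ]
   ],
   "connective": "OR",
   "then": [
    "r1b",
    "medium"
   ]
  },
  {
   "if": [
    [
     "calc_primacy",
     "intermediate"
    ]
   ],
   "connective": "AND",
   "then": [
    "r1b",
    "medium"
   ]
  },
  {
   "if": [
    [
     "calc_shape",
     "suspicious"
    ],
    [
     "calc_distribution",
     "suspicious"
    ]
   ],
   "connective": "OR",
   "then": [
    "r1b",
    "high"
   ]
  },
  {
   "if": [
    [
     "calc_primacy",
     "suspicious"
    ],
    [
     "calc_shape",
     "intermediate"
    ]
   ],
   "connective": "AND",
   "then": [
    "r1b",
    "high"
   ]
  }
 ]
}
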