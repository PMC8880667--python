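{
 "name": "es1c-asymmetry-distortion",
 "version": "1",
 "inputs": [
  {
   "name": "asym_type",
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
   "name": "distortion_primacy",
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
  "name": "r1c",
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
     "asym_type",
     "benign"
    ],
    [
     "distortion_primacy",
     "benign"
    ]
   ],
   "connective": "AND",
   "then": [
    "r1c",
    "low"
   ]
  },
  {
   "if": [
    [
     "asym_type",
     "intermediate"
    ],
    [
     "distortion_primacy",
     "intermediate"
    ]
   ],
   "connective": "OR",
   "then": [
    "r1c",
    "medium"
   ]
  },
  {
   "if": [
    [
     "asym_type",
     "suspicious"
    ],
    [
     "distortion_primacy",
     "suspicious"
    ]
   ],
   "connective": "OR",
   "then": [
    "r1c",
    "high"
   ]
  }
 ]
}
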