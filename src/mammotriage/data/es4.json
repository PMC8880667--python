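{
 "name": "es4-history",
 "version": "1",
 "inputs": [
  {
   "name": "r3",
   "universe": [
    0,
    100
   ],
   "terms": {
    "low": {
     "kind": "trapezoidal",
     "params": [
      0.0,
      0.0,
      20.0,
      40.0
     ]
    },
    "medium": {
     "kind": "trapezoidal",
     "params": [
      25.0,
      40.0,
      60.0,
      75.0
     ]
    },
    "high": {
     "kind": "trapezoidal",
     "params": [
      60.0,
      80.0,
      100.0,
      100.0
     ]
    }
   }
  },
  {
   "name": "age",
   "universe": [
    18,
    100
   ],
   "terms": {
    "young": {
     "kind": "triangular",
     "params": [
      18.0,
      18.0,
      45.0
     ]
    },
    "middle": {
     "kind": "triangular",
     "params": [
      35.0,
      57.0,
      80.0
     ]
    },
    "old": {
     "kind": "triangular",
     "params": [
      65.0,
      100.0,
      100.0
     ]
    }
   }
  },
  {
   "name": "patient_history",
   "universe": [
    0,
    10
   ],
   "terms": {
    "no": {
     "kind": "triangular",
     "params": [
      0.0,
      0.0,
      6.0
     ]
    },
    "yes": {
     "kind": "triangular",
     "params": [
      4.0,
      10.0,
      10.0
     ]
    }
   }
  },
  {
   "name": "family_history",
   "universe": [
    0,
    10
   ],
   "terms": {
    "none": {
     "kind": "triangular",
     "params": [
      0.0,
      0.0,
      4.0
     ]
    },
    "minor": {
     "kind": "triangular",
     "params": [
      2.0,
      5.0,
      8.0
     ]
    },
    "major": {
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
  "name": "r4",
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
     "r3",
     "low"
    ]
   ],
   "connective": "AND",
   "then": [
    "r4",
    "low"
   ]
  },
  {
   "if": [
    [
     "r3",
     "medium"
    ]
   ],
   "connective": "AND",
   "then": [
    "r4",
    "medium"
   ]
  },
  {
   "if": [
    [
     "r3",
     "high"
    ]
   ],
   "connective": "AND",
   "then": [
    "r4",
    "high"
   ]
  },
  {
   "if": [
    [
     "r3",
     "medium"
    ],
    [
     "patient_history",
     "yes"
    ]
   ],
   "connective": "AND",
   "then": [
    "r4",
    "high"
   ]
  },
  {
   "if": [
    [
     "r3",
     "medium"
    ],
    [
     "family_history",
     "major"
    ]
   ],
   "connective": "AND",
   "then": [
    "r4",
    "high"
   ]
  },
  {
   "if": [
    [
     "r3",
     "low"
    ],
    [
     "family_history",
     "major"
    ]
   ],
   "connective": "AND",
   "then": [
    "r4",
    "medium"
   ]
  },
  {
   "if": [
    [
     "r3",
     "medium"
    ],
    [
     "age",
     "old"
    ]
   ],
   "connective": "AND",
   "then": [
    "r4",
    "high"
   ]
  }
 ]
}
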