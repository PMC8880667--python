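{
 "name": "es3-composition",
 "version": "1",
 "inputs": [
  {
   "name": "r2",
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
   "name": "breast_density",
   "universe": [
    0,
    10
   ],
   "terms": {
    "low": {
     "kind": "triangular",
     "params": [
      0.0,
      0.0,
      4.0
     ]
    },
    "moderate": {
     "kind": "triangular",
     "params": [
      2.0,
      5.0,
      8.0
     ]
    },
    "high": {
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
  "name": "r3",
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
     "r2",
     "low"
    ]
   ],
   "connective": "AND",
   "then": [
    "r3",
    "low"
   ]
  },
  {
   "if": [
    [
     "r2",
     "medium"
    ]
   ],
   "connective": "AND",
   "then": [
    "r3",
    "medium"
   ]
  },
  {
   "if": [
    [
     "r2",
     "high"
    ]
   ],
   "connective": "AND",
   "then": [
    "r3",
    "high"
   ]
  },
  {
   "if": [
    [
     "r2",
     "medium"
    ],
    [
     "breast_density",
     "high"
    ]
   ],
   "connective": "AND",
   "then": [
    "r3",
    "high"
   ]
  },
  {
   "if": [
    [
     "r2",
     "low"
    ],
    [
     "breast_density",
     "high"
    ]
   ],
   "connective": "AND",
   "then": [
    "r3",
    "medium"
   ]
  }
 ]
}
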