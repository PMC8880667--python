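{
 "name": "es2-birads",
 "version": "1",
 "inputs": [
  {
   "name": "r1a",
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
   "name": "r1b",
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
   "name": "r1c",
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
   "name": "birads",
   "universe": [
    0,
    8
   ],
   "terms": {
    "low": {
     "kind": "triangular",
     "params": [
      0.0,
      0.0,
      3.0
     ]
    },
    "moderate": {
     "kind": "triangular",
     "params": [
      2.0,
      4.0,
      6.0
     ]
    },
    "high": {
     "kind": "triangular",
     "params": [
      5.0,
      8.0,
      8.0
     ]
    }
   }
  }
 ],
 "output": {
  "name": "r2",
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
     "r1a",
     "low"
    ],
    [
     "r1b",
     "low"
    ],
    [
     "r1c",
     "low"
    ],
    [
     "birads",
     "low"
    ]
   ],
   "connective": "AND",
   "then": [
    "r2",
    "low"
   ]
  },
  {
   "if": [
    [
     "birads",
     "moderate"
    ]
   ],
   "connective": "AND",
   "then": [
    "r2",
    "medium"
   ]
  },
  {
   "if": [
    [
     "r1a",
     "medium"
    ],
    [
     "r1b",
     "medium"
    ],
    [
     "r1c",
     "medium"
    ]
   ],
   "connective": "OR",
   "then": [
    "r2",
    "medium"
   ]
  },
  {
   "if": [
    [
     "birads",
     "high"
    ]
   ],
   "connective": "AND",
   "then": [
    "r2",
    "high"
   ]
  },
  {
   "if": [
    [
     "r1a",
     "high"
    ],
    [
     "r1b",
     "high"
    ],
    [
     "r1c",
     "high"
    ]
   ],
   "connective": "OR",
   "then": [
    "r2",
    "high"
   ]
  },
  {
   "if": [
    [
     "birads",
     "moderate"
    ],
    [
     "r1c",
     "medium"
    ]
   ],
   "connective": "AND",
   "then": [
    "r2",
    "high"
   ]
  }
 ]
}
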