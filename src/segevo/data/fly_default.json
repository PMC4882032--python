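{
 "schema_version": 1,
 "grid": {
  "n_bins": 200
 },
 "maternal": {
  "params": {
   "bcd_lambda": 0.15,
   "cad_k": 0.01,
   "cad_n": 2.0,
   "tll_x": 0.86,
   "tll_w": 0.022,
   "hkb_x": 0.95,
   "hkb_w": 0.01
  },
  "shift": 0.0
 },
 "uniform_activator": 1.0,
 "include_ftz": true,
 "loss_threshold": 0.05,
 "kernels": {
  "hb_ant": {
   "max_rate": 1.3,
   "decay": 1.0,
   "activators": [
    [
     "bcd",
     0.0483,
     8
    ]
   ],
   "repressors": [
    [
     "kni",
     1.5,
     2
    ]
   ],
   "evolvable": [
    "act:bcd:K",
    "max_rate",
    "rep:kni:K"
   ]
  },
  "hb_post": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "cad",
     0.8,
     8
    ]
   ],
   "repressors": [
    [
     "kni",
     0.3,
     4
    ],
    [
     "tll",
     3.0,
     2
    ],
    [
     "hkb",
     0.12,
     6
    ]
   ],
   "evolvable": [
    "act:cad:K",
    "max_rate",
    "rep:hkb:K",
    "rep:kni:K",
    "rep:tll:K"
   ]
  },
  "Kr": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "UNIFORM",
     0.2,
     2
    ]
   ],
   "repressors": [
    [
     "hb",
     0.4,
     8
    ],
    [
     "kni",
     0.25,
     4
    ],
    [
     "gt",
     0.2,
     6
    ],
    [
     "tll",
     0.05,
     4
    ]
   ],
   "evolvable": [
    "max_rate",
    "rep:gt:K",
    "rep:hb:K",
    "rep:kni:K",
    "rep:tll:K"
   ]
  },
  "kni": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "cad",
     0.197,
     3
    ]
   ],
   "repressors": [
    [
     "hb",
     0.15,
     6
    ],
    [
     "Kr",
     1.2,
     2
    ],
    [
     "gt",
     0.18,
     2
    ],
    [
     "tll",
     0.08,
     4
    ]
   ],
   "evolvable": [
    "act:cad:K",
    "max_rate",
    "rep:Kr:K",
    "rep:gt:K",
    "rep:hb:K",
    "rep:tll:K"
   ]
  },
  "gt_ant": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "bcd",
     0.0498,
     4
    ]
   ],
   "repressors": [
    [
     "Kr",
     0.3,
     4
    ]
   ],
   "evolvable": [
    "act:bcd:K",
    "max_rate",
    "rep:Kr:K"
   ]
  },
  "gt_post": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "cad",
     0.466,
     4
    ]
   ],
   "repressors": [
    [
     "Kr",
     0.8,
     2
    ],
    [
     "kni",
     0.6,
     4
    ],
    [
     "hb",
     0.35,
     4
    ],
    [
     "tll",
     0.22,
     4
    ],
    [
     "hkb",
     0.1,
     4
    ]
   ],
   "evolvable": [
    "act:cad:K",
    "max_rate",
    "rep:Kr:K",
    "rep:hb:K",
    "rep:hkb:K",
    "rep:kni:K",
    "rep:tll:K"
   ]
  },
  "eve2": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "bcd",
     0.04,
     6
    ]
   ],
   "repressors": [
    [
     "gt",
     0.6,
     6
    ],
    [
     "Kr",
     0.05,
     6
    ]
   ],
   "evolvable": [
    "act:bcd:K",
    "max_rate",
    "rep:Kr:K",
    "rep:gt:K"
   ]
  },
  "eve37": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "UNIFORM",
     0.2,
     2
    ]
   ],
   "repressors": [
    [
     "hb",
     0.28,
     8
    ],
    [
     "kni",
     0.02,
     4
    ],
    [
     "tll",
     0.7,
     4
    ]
   ],
   "evolvable": [
    "max_rate",
    "rep:hb:K",
    "rep:kni:K",
    "rep:tll:K"
   ]
  },
  "eve46": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "UNIFORM",
     0.2,
     2
    ]
   ],
   "repressors": [
    [
     "hb",
     0.04,
     8
    ],
    [
     "kni",
     0.12,
     4
    ],
    [
     "tll",
     0.05,
     4
    ]
   ],
   "evolvable": [
    "max_rate",
    "rep:hb:K",
    "rep:kni:K",
    "rep:tll:K"
   ]
  },
  "eve5": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "UNIFORM",
     0.2,
     2
    ]
   ],
   "repressors": [
    [
     "Kr",
     0.06,
     4
    ],
    [
     "gt",
     0.15,
     4
    ],
    [
     "tll",
     0.04,
     4
    ]
   ],
   "evolvable": [
    "max_rate",
    "rep:Kr:K",
    "rep:gt:K",
    "rep:tll:K"
   ]
  },
  "ftz15": {
   "max_rate": 0.4,
   "decay": 1.0,
   "activators": [
    [
     "UNIFORM",
     0.2,
     2
    ]
   ],
   "repressors": [
    [
     "bcd",
     0.045,
     8
    ],
    [
     "Kr",
     0.12,
     4
    ],
    [
     "kni",
     0.45,
     8
    ],
    [
     "gt",
     0.35,
     8
    ],
    [
     "hb",
     0.25,
     8
    ],
    [
     "tll",
     0.12,
     4
    ]
   ],
   "evolvable": [
    "max_rate",
    "rep:Kr:K",
    "rep:bcd:K",
    "rep:gt:K",
    "rep:hb:K",
    "rep:kni:K",
    "rep:tll:K"
   ]
  },
  "ftz27": {
   "max_rate": 0.4,
   "decay": 1.0,
   "activators": [
    [
     "UNIFORM",
     0.2,
     2
    ]
   ],
   "repressors": [
    [
     "gt",
     0.22,
     8
    ],
    [
     "Kr",
     0.8,
     8
    ],
    [
     "kni",
     0.3,
     4
    ],
    [
     "tll",
     0.1,
     4
    ]
   ],
   "evolvable": [
    "max_rate",
    "rep:Kr:K",
    "rep:gt:K",
    "rep:kni:K",
    "rep:tll:K"
   ]
  },
  "ftz36": {
   "max_rate": 0.4,
   "decay": 1.0,
   "activators": [
    [
     "UNIFORM",
     0.2,
     2
    ]
   ],
   "repressors": [
    [
     "hb",
     0.18,
     8
    ],
    [
     "kni",
     0.035,
     4
    ],
    [
     "tll",
     0.2,
     4
    ]
   ],
   "evolvable": [
    "max_rate",
    "rep:hb:K",
    "rep:kni:K",
    "rep:tll:K"
   ]
  },
  "ftz4zebra": {
   "max_rate": 1.0,
   "decay": 1.0,
   "activators": [
    [
     "UNIFORM",
     0.2,
     2
    ]
   ],
   "repressors": [
    [
     "eve",
     0.3,
     6
    ]
   ],
   "evolvable": [
    "max_rate",
    "rep:eve:K"
   ]
  }
 }
}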