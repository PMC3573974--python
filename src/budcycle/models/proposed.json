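{
 "name": "proposed",
 "semantics": "multilevel",
 "nodes": [
  {
   "name": "Cln3",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "1/2"
   ]
  },
  {
   "name": "MBF",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "1/2"
   ]
  },
  {
   "name": "SBF",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "1/2"
   ]
  },
  {
   "name": "Cln2",
   "max_level": 1,
   "self_degrading": true,
   "thresholds": [
    "1/2"
   ]
  },
  {
   "name": "Cdh1",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "1/2"
   ]
  },
  {
   "name": "Swi5",
   "max_level": 2,
   "self_degrading": true,
   "thresholds": [
    "1/2",
    "3/2"
   ]
  },
  {
   "name": "Cdc20",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "1/2"
   ]
  },
  {
   "name": "Clb5",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "1/2"
   ]
  },
  {
   "name": "Sic1",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "1/2"
   ]
  },
  {
   "name": "Clb2",
   "max_level": 2,
   "self_degrading": false,
   "thresholds": [
    "1/2",
    "3/2"
   ]
  },
  {
   "name": "Mcm1",
   "max_level": 1,
   "self_degrading": true,
   "thresholds": [
    "1/2"
   ]
  }
 ],
 "edges": [
  {
   "from": "Cdc20",
   "to": "Cdh1",
   "weight": "1"
  },
  {
   "from": "Cdc20",
   "to": "Clb2",
   "weight": "-1/3"
  },
  {
   "from": "Cdc20",
   "to": "Clb5",
   "weight": "-1"
  },
  {
   "from": "Cdc20",
   "to": "Sic1",
   "weight": "1/3"
  },
  {
   "from": "Cdc20",
   "to": "Swi5",
   "weight": "3"
  },
  {
   "from": "Cdh1",
   "to": "Cdc20",
   "weight": "-1"
  },
  {
   "from": "Cdh1",
   "to": "Clb2",
   "weight": "-1/3"
  },
  {
   "from": "Cdh1",
   "to": "Clb5",
   "weight": "-3"
  },
  {
   "from": "Cdh1",
   "to": "Sic1",
   "weight": "1/3"
  },
  {
   "from": "Clb2",
   "to": "Cdc20",
   "weight": "1/3"
  },
  {
   "from": "Clb2",
   "to": "Cdh1",
   "weight": "-3"
  },
  {
   "from": "Clb2",
   "to": "MBF",
   "weight": "-1"
  },
  {
   "from": "Clb2",
   "to": "Mcm1",
   "weight": "1"
  },
  {
   "from": "Clb2",
   "to": "SBF",
   "weight": "-1"
  },
  {
   "from": "Clb2",
   "to": "Sic1",
   "weight": "-1/3"
  },
  {
   "from": "Clb2",
   "to": "Swi5",
   "weight": "-1/3"
  },
  {
   "from": "Clb5",
   "to": "Cdc20",
   "weight": "-1/3"
  },
  {
   "from": "Clb5",
   "to": "Clb2",
   "weight": "1"
  },
  {
   "from": "Clb5",
   "to": "Mcm1",
   "weight": "1/3"
  },
  {
   "from": "Clb5",
   "to": "Sic1",
   "weight": "-1"
  },
  {
   "from": "Cln2",
   "to": "Cdh1",
   "weight": "-1"
  },
  {
   "from": "Cln2",
   "to": "Sic1",
   "weight": "-1"
  },
  {
   "from": "Cln3",
   "to": "MBF",
   "weight": "3"
  },
  {
   "from": "Cln3",
   "to": "SBF",
   "weight": "3"
  },
  {
   "from": "MBF",
   "to": "Clb5",
   "weight": "3"
  },
  {
   "from": "MBF",
   "to": "Cln3",
   "weight": "-1/3"
  },
  {
   "from": "Mcm1",
   "to": "Cdc20",
   "weight": "3"
  },
  {
   "from": "Mcm1",
   "to": "Clb2",
   "weight": "1"
  },
  {
   "from": "Mcm1",
   "to": "Swi5",
   "weight": "1"
  },
  {
   "from": "SBF",
   "to": "Cln2",
   "weight": "1"
  },
  {
   "from": "SBF",
   "to": "Cln3",
   "weight": "-1/3"
  },
  {
   "from": "Sic1",
   "to": "Cdc20",
   "weight": "-1/3"
  },
  {
   "from": "Sic1",
   "to": "Clb2",
   "weight": "-1/3"
  },
  {
   "from": "Sic1",
   "to": "Clb5",
   "weight": "-3"
  },
  {
   "from": "Swi5",
   "to": "Sic1",
   "weight": "1/3"
  }
 ],
 "states": {
  "stationary_g1": {
   "Cdh1": 1,
   "Sic1": 1
  },
  "stimulated_g1": {
   "Cdh1": 1,
   "Cln3": 1,
   "Sic1": 1
  }
 }
}
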