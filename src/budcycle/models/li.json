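{
 "name": "li",
 "semantics": "li_binary",
 "nodes": [
  {
   "name": "Cln3",
   "max_level": 1,
   "self_degrading": true,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "MBF",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "SBF",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "Cln2",
   "max_level": 1,
   "self_degrading": true,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "Cdh1",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "Swi5",
   "max_level": 1,
   "self_degrading": true,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "Cdc20",
   "max_level": 1,
   "self_degrading": true,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "Clb5",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "Sic1",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "Clb2",
   "max_level": 1,
   "self_degrading": false,
   "thresholds": [
    "0"
   ]
  },
  {
   "name": "Mcm1",
   "max_level": 1,
   "self_degrading": true,
   "thresholds": [
    "0"
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
   "weight": "-1"
  },
  {
   "from": "Cdc20",
   "to": "Clb5",
   "weight": "-1"
  },
  {
   "from": "Cdc20",
   "to": "Sic1",
   "weight": "1"
  },
  {
   "from": "Cdc20",
   "to": "Swi5",
   "weight": "1"
  },
  {
   "from": "Cdh1",
   "to": "Clb2",
   "weight": "-1"
  },
  {
   "from": "Clb2",
   "to": "Cdc20",
   "weight": "1"
  },
  {
   "from": "Clb2",
   "to": "Cdh1",
   "weight": "-1"
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
   "weight": "-1"
  },
  {
   "from": "Clb2",
   "to": "Swi5",
   "weight": "-1"
  },
  {
   "from": "Clb5",
   "to": "Cdh1",
   "weight": "-1"
  },
  {
   "from": "Clb5",
   "to": "Clb2",
   "weight": "1"
  },
  {
   "from": "Clb5",
   "to": "Mcm1",
   "weight": "1"
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
   "weight": "1"
  },
  {
   "from": "Cln3",
   "to": "SBF",
   "weight": "1"
  },
  {
   "from": "MBF",
   "to": "Clb5",
   "weight": "1"
  },
  {
   "from": "Mcm1",
   "to": "Cdc20",
   "weight": "1"
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
   "from": "Sic1",
   "to": "Clb2",
   "weight": "-1"
  },
  {
   "from": "Sic1",
   "to": "Clb5",
   "weight": "-1"
  },
  {
   "from": "Swi5",
   "to": "Sic1",
   "weight": "1"
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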