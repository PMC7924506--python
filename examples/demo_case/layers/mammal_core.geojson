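{
 "type": "Polygon",
 "coordinates": [
  [
   [
    10000.0,
    6000.0
   ],
   [
    9951.963201008075,
    5512.274194959679
   ],
   [
    9809.698831278216,
    5043.291419087275
   ],
   [
    9578.674030756363,
    4611.074417450995
   ],
   [
    9267.766952966369,
    4232.233047033631
   ],
   [
    8888.925582549005,
    3921.325969243637
   ],
   [
    8456.708580912724,
    3690.301168721783
   ],
   [
    7987.725805040321,
    3548.036798991924
   ],
   [
    7500.0,
    3500.0
   ],
   [
    7012.274194959679,
    3548.036798991924
   ],
   [
    6543.291419087276,
    3690.301168721783
   ],
   [
    6111.074417450995,
    3921.3259692436363
   ],
   [
    5732.233047033631,
    4232.233047033631
   ],
   [
    5421.325969243637,
    4611.074417450995
   ],
   [
    5190.301168721783,
    5043.291419087275
   ],
   [
    5048.036798991924,
    5512.274194959678
   ],
   [
    5000.0,
    6000.0
   ],
   [
    5048.036798991924,
    6487.725805040321
   ],
   [
    5190.301168721782,
    6956.708580912724
   ],
   [
    5421.325969243637,
    7388.925582549005
   ],
   [
    5732.233047033631,
    7767.766952966369
   ],
   [
    6111.074417450995,
    8078.674030756363
   ],
   [
    6543.291419087274,
    8309.698831278216
   ],
   [
    7012.274194959678,
    8451.963201008075
   ],
   [
    7500.0,
    8500.0
   ],
   [
    7987.725805040321,
    8451.963201008075
   ],
   [
    8456.708580912726,
    8309.698831278216
   ],
   [
    8888.925582549004,
    8078.674030756363
   ],
   [
    9267.766952966369,
    7767.766952966369
   ],
   [
    9578.674030756363,
    7388.925582549005
   ],
   [
    9809.698831278216,
    6956.708580912726
   ],
   [
    9951.963201008075,
    6487.725805040322
   ],
   [
    10000.0,
    6000.0
   ]
  ]
 ]
}
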